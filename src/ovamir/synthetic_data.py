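"""Self-contained toy study generator.

Builds a small genome with planted miRNA precursors, novel hairpin loci,
contaminant ncRNAs and exon/intron/repeat features, then simulates two
adapter-ligated fixed-cycle FASTQ libraries with known per-miRNA
abundances, planted fold changes and per-read provenance labels, plus a
matching qPCR CT table.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io
from .preprocess import classify_insert, find_adapter3
from .references import ReferenceBundle

# Illumina TruSeq small-RNA adapters; the protocol itself names none, so
# these are config knobs with conventional defaults.
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"

DEFAULT_LENGTH_PROFILE = {20: 0.10, 21: 0.20, 22: 0.40, 23: 0.20, 24: 0.10}

DEFAULT_CONTAMINATION = {
    "rRNA": 0.020, "tRNA": 0.010, "snRNA": 0.004, "snoRNA": 0.004,
    "scRNA": 0.002, "srpRNA": 0.002,
    "repeat": 0.004, "exon": 0.004, "intron": 0.004,
    "unann": 0.008, "novel": 0.006,
    "polyA": 0.002, "short": 0.002, "low_quality": 0.002,
    "adapter3_null": 0.001, "insert_null": 0.001, "adapter5": 0.002,
}

NCRNA_TYPES = ("rRNA", "tRNA", "snRNA", "snoRNA", "scRNA", "srpRNA")

HIGH_QUAL = "I"  # Phred 40
LOW_QUAL = "#"   # Phred 2


@dataclass
class SimulationConfig:
    seed: int = 1
    n_mirnas: int = 50
    n_novel_hairpins: int = 3
    library_depths: tuple[int, int] = (10_000, 10_000)
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    contamination_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTAMINATION))
    de_fraction: float = 0.1
    planted_log2fc: float = 2.0
    length_profile: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_PROFILE))
    read_length: int = 36
    abundance_sigma: float = 1.0
    star_mismatches: int = 1
    n_genes: int = 60
    n_go_terms_per_ontology: int = 8
    n_pathways: int = 12
    ct_noise_sd: float = 0.25
    genome_length: int | None = None  # optional padding / capacity check

    def validate(self) -> None:
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be >= 1")
        if any(d < 0 for d in self.library_depths):
            raise ValueError("library depths must be non-negative")
        fracs = self.contamination_fractions
        if any(not 0 <= f <= 1 for f in fracs.values()):
            raise ValueError("contamination fractions must lie in [0, 1]")
        if sum(fracs.values()) >= 1:
            raise ValueError("contamination fractions must sum to < 1 "
                             "(the remainder is the miRNA signal)")
        if abs(sum(self.length_profile.values()) - 1.0) > 1e-9:
            raise ValueError("length_profile must sum to 1")
        if any(not 18 <= k <= 30 for k in self.length_profile):
            raise ValueError("length_profile lengths must lie in [18, 30]")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "library_depths" in raw:
            raw["library_depths"] = tuple(raw["library_depths"])
        if "length_profile" in raw:
            raw["length_profile"] = {int(k): float(v) for k, v in raw["length_profile"].items()}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["library_depths"] = list(self.library_depths)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class NovelLocus:
    locus_id: str
    chrom: str
    start: int        # precursor span, 0-based half-open
    end: int
    strand: str
    precursor: str
    mature: str
    mature_start: int  # genomic start of the mature arm


@dataclass
class TruthRecord:
    mirna_table: pd.DataFrame       # id, sequence, is_de, direction, expected/realized counts
    novel_loci: list[NovelLocus]
    novel_counts: pd.DataFrame      # locus_id, realized_lib1, realized_lib2
    category_counts: list[Counter]  # per-library provenance tallies
    read_labels: list[list[str]]    # per-library, read order

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        io.write_tsv(d / "truth_mirna.tsv", self.mirna_table)
        io.write_tsv(d / "truth_novel.tsv", pd.DataFrame(
            [dataclasses.asdict(n) for n in self.novel_loci]))
        io.write_tsv(d / "truth_novel_counts.tsv", self.novel_counts)
        rows = []
        for lib, counts in enumerate(self.category_counts, start=1):
            for cat in sorted(counts):
                rows.append({"library": f"lib{lib}", "category": cat, "reads": counts[cat]})
        io.write_tsv(d / "truth_categories.tsv",
                     pd.DataFrame(rows, columns=["library", "category", "reads"]))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _trimmer_safe(insert: str, adapter3: str, adapter5: str,
                  expect: str | None = None) -> bool:
    """True if the cleaner will route this insert to ``expect`` (None =
    clean) and trims the simulated read exactly at the insert/adapter
    junction.  The simulator resamples unsafe inserts so per-read truth
    labels stay exact."""
    if insert and find_adapter3(insert + adapter3, adapter3) != len(insert):
        return False  # spurious adapter match inside or at the junction
    return classify_insert(insert, adapter5) == expect


def _safe_insert(rng: np.random.Generator, make, adapter3: str, adapter5: str,
                 expect: str | None = None, tries: int = 50) -> str:
    insert = make()
    for _ in range(tries):
        if _trimmer_safe(insert, adapter3, adapter5, expect):
            return insert
        insert = make()
    return insert


def _draw_length(rng: np.random.Generator, profile: dict[int, float],
                 lo: int | None = None, hi: int | None = None) -> int:
    items = [(k, v) for k, v in sorted(profile.items())
             if (lo is None or k >= lo) and (hi is None or k <= hi)]
    lengths = np.array([k for k, _ in items])
    probs = np.array([v for _, v in items], dtype=float)
    probs /= probs.sum()
    return int(rng.choice(lengths, p=probs))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    if n_subs <= 0:
        return seq
    chars = list(seq)
    positions = rng.choice(len(chars), size=min(n_subs, len(chars)), replace=False)
    for pos in positions:
        chars[pos] = rng.choice([b for b in "ACGT" if b != chars[pos]])
    return "".join(chars)


def _make_hairpin(rng: np.random.Generator, mature: str, star_mismatches: int,
                  loop_len: int = 8) -> str:
    """Precursor = mature arm + loop + near-reverse-complement star arm."""
    loop = _random_seq(rng, loop_len)
    star = _mutate(rng, io.revcomp(mature), star_mismatches)
    return mature + loop + star


@dataclass
class StudyReferences:
    """Reference bundle plus the planted-layout bookkeeping the simulator
    (but not the analysis pipeline) is allowed to see."""
    bundle: ReferenceBundle
    novel_loci: list[NovelLocus]
    mirna_ids: list[str]
    feature_regions: dict[str, list[tuple[int, int, str]]]  # type -> [(start, end, strand)]


def build_reference_set(config: SimulationConfig) -> StudyReferences:
    """Genome, annotation and reference FASTAs with planted loci."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    spacer = 120

    segments: list[str] = []
    cursor = 0

    def push(seq: str) -> int:
        nonlocal cursor
        start = cursor
        segments.append(seq)
        cursor += len(seq)
        return start

    def push_spacer() -> None:
        push(_random_seq(rng, spacer))

    mature: dict[str, str] = {}
    precursor: dict[str, str] = {}
    features: list[dict] = []
    seen: set[str] = set()

    def fresh_mature(lo: int | None = None, hi: int | None = None) -> str:
        while True:
            m = _safe_insert(
                rng,
                lambda: _random_seq(rng, _draw_length(rng, config.length_profile, lo, hi)),
                config.adapter3, config.adapter5)
            if m not in seen:
                seen.add(m)
                return m

    push_spacer()
    for i in range(1, config.n_mirnas + 1):
        mid = f"mir-{i:04d}"
        m = fresh_mature()
        pre = _make_hairpin(rng, m, config.star_mismatches)
        start = push(pre)
        mature[mid] = m
        precursor[f"{mid}-pre"] = pre
        features.append({"chrom": chrom, "start": start, "end": start + len(pre),
                         "name": f"mirna:{mid}", "score": 0, "strand": "+"})
        push_spacer()

    novel_loci: list[NovelLocus] = []
    for i in range(1, config.n_novel_hairpins + 1):
        m = fresh_mature(lo=20, hi=24)
        pre = _make_hairpin(rng, m, config.star_mismatches)
        start = push(pre)
        novel_loci.append(NovelLocus(
            locus_id=f"novel-locus-{i}", chrom=chrom, start=start,
            end=start + len(pre), strand="+", precursor=pre, mature=m,
            mature_start=start))
        push_spacer()

    ncrna: dict[str, str] = {}
    for subtype in NCRNA_TYPES:
        for j in (1, 2):
            seq = _random_seq(rng, int(rng.integers(80, 150)))
            rec_id = f"{subtype}-{j}"
            ncrna[rec_id] = seq
            start = push(seq)
            features.append({"chrom": chrom, "start": start, "end": start + len(seq),
                             "name": f"ncrna:{rec_id}", "score": 0, "strand": "+"})
            push_spacer()

    feature_regions: dict[str, list[tuple[int, int, str]]] = {
        "repeat": [], "exon": [], "intron": []}
    for ftype, count, length in (("repeat", 3, 100), ("exon", 4, 120), ("intron", 4, 120)):
        for j in range(1, count + 1):
            seq = _random_seq(rng, length)
            start = push(seq)
            strand = "+"
            features.append({"chrom": chrom, "start": start, "end": start + length,
                             "name": f"{ftype}:{ftype}{j}", "score": 0, "strand": strand})
            feature_regions[ftype].append((start, start + length, strand))
            push_spacer()

    genome_seq = "".join(segments)
    if config.genome_length is not None:
        if config.genome_length < len(genome_seq):
            raise ValueError(
                f"genome_length {config.genome_length} too small to host all "
                f"features (need {len(genome_seq)})")
        genome_seq += _random_seq(rng, config.genome_length - len(genome_seq))

    utrs = {f"gene{g:03d}": _random_seq(rng, int(rng.integers(150, 400)))
            for g in range(1, config.n_genes + 1)}

    go_rows = []
    for ont in ("cellular_component", "molecular_function", "biological_process"):
        terms = [f"{ont}:{t:02d}" for t in range(1, config.n_go_terms_per_ontology + 1)]
        for gene in utrs:
            for term in rng.choice(terms, size=int(rng.integers(1, 3)), replace=False):
                go_rows.append((gene, term))
    pathways = [f"path{t:02d}" for t in range(1, config.n_pathways + 1)]
    pathway_rows = []
    for gene in utrs:
        for term in rng.choice(pathways, size=int(rng.integers(1, 3)), replace=False):
            pathway_rows.append((gene, term))

    bundle = ReferenceBundle(
        genome={chrom: genome_seq},
        features=pd.DataFrame(features, columns=io.BED_COLUMNS),
        mature=mature, precursor=precursor, ncrna=ncrna, utrs=utrs,
        go_map=pd.DataFrame(go_rows, columns=["gene", "term"]),
        pathway_map=pd.DataFrame(pathway_rows, columns=["gene", "term"]),
    )
    return StudyReferences(bundle=bundle, novel_loci=novel_loci,
                           mirna_ids=sorted(mature), feature_regions=feature_regions)


def planted_de_table(config: SimulationConfig, refs: StudyReferences) -> pd.DataFrame:
    """Deterministic DE plan: the first floor(de_fraction * n) miRNAs (id
    order) carry the planted fold change, alternating up/down in lib2."""
    n_de = int(np.floor(config.de_fraction * config.n_mirnas))
    rows = []
    for i, mid in enumerate(refs.mirna_ids):
        is_de = i < n_de
        direction = 0 if not is_de else (1 if i % 2 == 0 else -1)
        rows.append({"mirna_id": mid, "is_de": is_de, "direction": direction})
    return pd.DataFrame(rows)


def _read_from_insert(insert: str, adapter3: str, read_length: int,
                      qual_char: str = HIGH_QUAL) -> tuple[str, str]:
    padding = (adapter3 * ((read_length // max(len(adapter3), 1)) + 2))
    seq = (insert + padding)[:read_length]
    return seq, qual_char * len(seq)


def simulate_libraries(config: SimulationConfig, refs: StudyReferences,
                       out_lib1: str | Path, out_lib2: str | Path,
                       ) -> TruthRecord:
    """Write two FASTQ libraries and return the machine-readable truth."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1_000_003)
    plan = planted_de_table(config, refs)
    mirna_ids = refs.mirna_ids
    n = len(mirna_ids)

    base = np.exp(config.abundance_sigma * rng.standard_normal(n))
    factor = np.power(2.0, config.planted_log2fc * plan["direction"].to_numpy())
    weights = {0: base / base.sum(), 1: (base * factor) / (base * factor).sum()}

    fracs = config.contamination_fractions
    categories = sorted(fracs)
    probs = np.array([fracs[c] for c in categories])
    mirna_prob = 1.0 - probs.sum()
    cat_list = categories + ["mirna"]
    cat_probs = np.append(probs, mirna_prob)

    genome = refs.bundle.genome
    chrom = next(iter(genome))
    ncrna_by_type = {t: [s for rid, s in refs.bundle.ncrna.items() if rid.startswith(t + "-")]
                     for t in NCRNA_TYPES}
    adapter3, adapter5 = config.adapter3, config.adapter5
    read_length = config.read_length

    def ncrna_fragment(subtype: str) -> str:
        def make() -> str:
            src = ncrna_by_type[subtype][int(rng.integers(len(ncrna_by_type[subtype])))]
            ln = int(rng.integers(18, 29))
            start = int(rng.integers(0, len(src) - ln + 1))
            return src[start : start + ln]
        return _safe_insert(rng, make, adapter3, adapter5)

    def feature_fragment(ftype: str) -> str:
        def make() -> str:
            lo, hi, _ = refs.feature_regions[ftype][
                int(rng.integers(len(refs.feature_regions[ftype])))]
            ln = int(rng.integers(18, 29))
            start = int(rng.integers(lo, hi - ln))
            frag = genome[chrom][start : start + ln]
            return io.revcomp(frag) if rng.random() < 0.3 else frag
        return _safe_insert(rng, make, adapter3, adapter5)

    mirna_counts = np.zeros((2, n), dtype=int)
    novel_counts = np.zeros((2, max(len(refs.novel_loci), 1)), dtype=int)
    category_counts: list[Counter] = [Counter(), Counter()]
    read_labels: list[list[str]] = [[], []]

    for lib in (0, 1):
        depth = config.library_depths[lib]
        reads: list[io.FastqRead] = []
        if depth > 0:
            labels = rng.choice(len(cat_list), size=depth, p=cat_probs)
            mirna_draws = rng.choice(n, size=depth, p=weights[lib])
        else:
            labels = np.empty(0, dtype=int)
            mirna_draws = np.empty(0, dtype=int)
        for ridx in range(depth):
            cat = cat_list[labels[ridx]]
            qual_char = HIGH_QUAL
            if cat == "mirna":
                mi = int(mirna_draws[ridx])
                insert = refs.bundle.mature[mirna_ids[mi]]
                mirna_counts[lib, mi] += 1
            elif cat == "novel" and refs.novel_loci:
                li = int(rng.integers(len(refs.novel_loci)))
                insert = refs.novel_loci[li].mature
                novel_counts[lib, li] += 1
            elif cat in NCRNA_TYPES:
                insert = ncrna_fragment(cat)
            elif cat in ("repeat", "exon", "intron"):
                insert = feature_fragment(cat)
            elif cat == "unann":
                insert = _safe_insert(
                    rng, lambda: _random_seq(rng, int(rng.integers(20, 25))),
                    adapter3, adapter5)
            elif cat == "polyA":
                insert = "A" * int(rng.integers(20, 27))
            elif cat == "short":
                insert = _safe_insert(
                    rng, lambda: _random_seq(rng, int(rng.integers(10, 18))),
                    adapter3, adapter5, expect="shorter_than_18nt")
            elif cat == "low_quality":
                insert = _random_seq(rng, 22)
                qual_char = LOW_QUAL
            elif cat == "adapter3_null":
                seq = _safe_insert(rng, lambda: _random_seq(rng, read_length),
                                   adapter3, adapter5, expect=None, tries=50)
                while find_adapter3(seq, adapter3) is not None:
                    seq = _random_seq(rng, read_length)
                reads.append(io.FastqRead(f"lib{lib + 1}_{ridx}", seq, HIGH_QUAL * read_length))
                category_counts[lib][cat] += 1
                read_labels[lib].append(cat)
                continue
            elif cat == "insert_null":
                insert = ""
            elif cat == "adapter5":
                insert = _safe_insert(
                    rng, lambda: adapter5[:12] + _random_seq(rng, 10),
                    adapter3, adapter5, expect="adapter5_contaminants")
            else:  # "novel" with no planted loci: fall back to a miRNA read
                mi = int(mirna_draws[ridx])
                insert = refs.bundle.mature[mirna_ids[mi]]
                mirna_counts[lib, mi] += 1
                cat = "mirna"
            seq, qual = _read_from_insert(insert, adapter3, read_length, qual_char)
            reads.append(io.FastqRead(f"lib{lib + 1}_{ridx}", seq, qual))
            category_counts[lib][cat] += 1
            read_labels[lib].append(cat)
        io.write_fastq(out_lib1 if lib == 0 else out_lib2, reads)

    mirna_frac = mirna_prob
    expected = {
        lib: config.library_depths[lib] * mirna_frac * weights[lib]
        for lib in (0, 1)
    }
    truth_mirna = plan.copy()
    truth_mirna["sequence"] = [refs.bundle.mature[m] for m in truth_mirna["mirna_id"]]
    truth_mirna["expected_lib1"] = expected[0]
    truth_mirna["expected_lib2"] = expected[1]
    truth_mirna["realized_lib1"] = mirna_counts[0]
    truth_mirna["realized_lib2"] = mirna_counts[1]

    novel_df = pd.DataFrame({
        "locus_id": [nl.locus_id for nl in refs.novel_loci],
        "realized_lib1": novel_counts[0, : len(refs.novel_loci)],
        "realized_lib2": novel_counts[1, : len(refs.novel_loci)],
    })
    return TruthRecord(mirna_table=truth_mirna, novel_loci=refs.novel_loci,
                       novel_counts=novel_df, category_counts=category_counts,
                       read_labels=read_labels)


def simulate_ct_table(config: SimulationConfig, truth: TruthRecord,
                      mirna_ids: Sequence[str] | None = None,
                      noise_sd: float | None = None) -> pd.DataFrame:
    """Triplicate CT table consistent with the planted abundances.

    CT drops one cycle per doubling of normalized abundance; the
    reference channel is constant up to the same Gaussian noise.
    """
    rng = np.random.default_rng(config.seed + 2_000_003)
    sd = config.ct_noise_sd if noise_sd is None else noise_sd
    table = truth.mirna_table.set_index("mirna_id")
    if mirna_ids is None:
        de_ids = list(table[table["is_de"]].index)
        null_ids = list(table[~table["is_de"]]
                        .sort_values("expected_lib1", ascending=False).index)
        mirna_ids = (de_ids + null_ids)[:5]
    depths = config.library_depths
    rows = []
    for mid in mirna_ids:
        for group, lib in (("control", 0), ("treatment", 1)):
            depth = max(depths[lib], 1)
            std = 1e6 * float(table.loc[mid, f"expected_lib{lib + 1}"]) / depth
            ct_base = 30.0 - np.log2(max(std, 0.01))
            row = {"mirna": mid, "group": group}
            for i in (1, 2, 3):
                row[f"rep{i}"] = round(float(ct_base + sd * rng.standard_normal()), 4)
            for i in (1, 2, 3):
                row[f"ref{i}"] = round(float(15.0 + sd * rng.standard_normal()), 4)
            rows.append(row)
    return pd.DataFrame(rows, columns=["mirna", "group", "rep1", "rep2", "rep3",
                                       "ref1", "ref2", "ref3"])


def simulate_study(config: SimulationConfig, outdir: str | Path) -> TruthRecord:
    """Full study generation to a directory (references, FASTQs, truth, CTs)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    refs = build_reference_set(config)
    refs.bundle.save(out / "references")
    truth = simulate_libraries(config, refs, out / "lib1.fastq", out / "lib2.fastq")
    truth.save(out / "truth")
    ct = simulate_ct_table(config, truth)
    io.write_tsv(out / "ct_table.tsv", ct)
    config.to_yaml(out / "config.yaml")
    return truth
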
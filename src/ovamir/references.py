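"""Reference bundle: the file set every annotation-dependent stage needs.

Layout (all plain text) inside a bundle directory::

    genome.fa        toy genome (one or more chromosomes)
    features.bed     6-column BED; feature type encoded as "type:name"
    mature.fa        known mature miRNAs
    precursor.fa     known precursors (one mature per precursor)
    ncrna.fa         contaminant ncRNAs; ids like "rRNA-1", "tRNA-2", ...
    utr.fa           3' UTR set keyed by gene id
    go_map.tsv       gene<TAB>GO-term (term ids carry an ontology prefix)
    pathway_map.tsv  gene<TAB>pathway
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io


@dataclass
class ReferenceBundle:
    genome: dict[str, str]
    features: pd.DataFrame  # BED columns; name = "type:identifier"
    mature: dict[str, str]
    precursor: dict[str, str]
    ncrna: dict[str, str]
    utrs: dict[str, str]
    go_map: pd.DataFrame
    pathway_map: pd.DataFrame

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceBundle":
        d = Path(directory)
        return cls(
            genome=io.read_fasta(d / "genome.fa"),
            features=io.read_bed(d / "features.bed"),
            mature=io.read_fasta(d / "mature.fa"),
            precursor=io.read_fasta(d / "precursor.fa"),
            ncrna=io.read_fasta(d / "ncrna.fa"),
            utrs=io.read_fasta(d / "utr.fa"),
            go_map=io.read_map(d / "go_map.tsv"),
            pathway_map=io.read_map(d / "pathway_map.tsv"),
        )

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        io.write_fasta(d / "genome.fa", sorted(self.genome.items()))
        io.write_bed(d / "features.bed", self.features)
        io.write_fasta(d / "mature.fa", sorted(self.mature.items()))
        io.write_fasta(d / "precursor.fa", sorted(self.precursor.items()))
        io.write_fasta(d / "ncrna.fa", sorted(self.ncrna.items()))
        io.write_fasta(d / "utr.fa", sorted(self.utrs.items()))
        self.go_map.to_csv(d / "go_map.tsv", sep="\t", header=False, index=False)
        self.pathway_map.to_csv(d / "pathway_map.tsv", sep="\t", header=False, index=False)


def feature_type(name: str) -> str:
    """Feature type from a BED name field of the form 'type:identifier'."""
    return name.split(":", 1)[0]


def ncrna_type(record_id: str) -> str:
    """ncRNA subtype from a reference id of the form 'subtype-n'."""
    return record_id.split("-", 1)[0]
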
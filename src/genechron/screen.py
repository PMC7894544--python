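"""Homolog screening filters.

Candidate gene sequences arrive as homology-search hit tables (BLAST tabular
dialect), multiple sequence alignments, and ortholog-group assignments; this
module applies the screening rules that decide which candidates enter the
gene trees:

* an e-value ceiling (default 1e-12, with per-gene overrides such as the
  stricter 1e-30 used to separate the nifD/nifK nitrogenase subunits, whose
  shared evolutionary history makes them cross-hit at looser thresholds);
* a minimum aligned fraction of the query (hits covering <50% of the query
  are discarded);
* presence of key catalytic/structural residues at stated alignment columns;
* confirmation of the ortholog-group assignment against an expected label.

The search engines themselves are out of scope: inputs are their outputs.
Thresholds are sided so that a hit at exactly the ceiling, or exactly the
minimum fraction, passes.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .synthetic import Alignment

__all__ = [
    "HitRecord",
    "ResidueSpec",
    "ScreenConfig",
    "AttritionLog",
    "filter_hits",
    "filter_hit_table",
    "check_key_residues",
    "confirm_annotation",
    "read_residue_spec",
]

GAP_CHARACTERS = set("-.")


@dataclasses.dataclass(frozen=True)
class HitRecord:
    """One homology-search hit."""

    query_id: str
    subject_id: str
    evalue: float
    alignment_length: int
    query_length: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value in hit {self.query_id}->{self.subject_id}")


@dataclasses.dataclass
class ResidueSpec:
    """Key residues required in a reference alignment.

    ``columns`` maps a 1-based alignment column index to the set of residues
    accepted there.  A gap character never satisfies a requirement.
    """

    gene: str
    columns: dict[int, frozenset[str]]

    def __post_init__(self) -> None:
        for col, allowed in self.columns.items():
            if col < 1:
                raise ValueError(f"residue spec column {col} must be >= 1")
            if not allowed:
                raise ValueError(f"residue spec column {col} has empty allowed set")


@dataclasses.dataclass
class ScreenConfig:
    default_evalue_ceiling: float = 1e-12
    per_gene_evalue_ceiling: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"nifD": 1e-30, "nifK": 1e-30}
    )
    min_length_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.default_evalue_ceiling <= 0:
            raise ValueError("e-value ceiling must be positive")
        for gene, ceiling in self.per_gene_evalue_ceiling.items():
            if ceiling <= 0:
                raise ValueError(f"e-value ceiling for {gene} must be positive")
        if not (0 < self.min_length_fraction <= 1):
            raise ValueError("min length fraction must lie in (0, 1]")

    def ceiling_for(self, gene: Optional[str]) -> float:
        if gene is not None and gene in self.per_gene_evalue_ceiling:
            return self.per_gene_evalue_ceiling[gene]
        return self.default_evalue_ceiling


@dataclasses.dataclass
class AttritionLog:
    """Counts in/out per filtering stage, for comparison with external tallies."""

    stages: list[dict] = dataclasses.field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int, **extra) -> None:
        self.stages.append({"stage": stage, "n_in": n_in, "n_out": n_out, **extra})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


def filter_hits(hits: Sequence[HitRecord], cfg: ScreenConfig,
                gene: Optional[str] = None,
                log: Optional[AttritionLog] = None) -> list[HitRecord]:
    """Retain hits meeting both the e-value ceiling and the length-fraction
    floor; order preserved, input untouched."""
    ceiling = cfg.ceiling_for(gene)
    kept = []
    for i, hit in enumerate(hits):
        if hit.query_length <= 0:
            raise ValueError(
                f"nonpositive query length in row {i} "
                f"({hit.query_id}->{hit.subject_id})"
            )
        if hit.evalue <= ceiling and hit.alignment_length / hit.query_length >= cfg.min_length_fraction:
            kept.append(hit)
    if log is not None:
        log.record("hit_filter", len(hits), len(kept), gene=gene or "", ceiling=ceiling)
    return kept


def filter_hit_table(table: pd.DataFrame, cfg: ScreenConfig,
                     gene: Optional[str] = None,
                     log: Optional[AttritionLog] = None) -> pd.DataFrame:
    """`filter_hits` over a BLAST-tabular DataFrame (outfmt-6 columns plus
    ``query_length``)."""
    if (table["query_length"] <= 0).any():
        bad = table.index[table["query_length"] <= 0][0]
        raise ValueError(f"nonpositive query length in row {bad}")
    ceiling = cfg.ceiling_for(gene)
    mask = (table["evalue"] <= ceiling) & (
        table["length"] / table["query_length"] >= cfg.min_length_fraction
    )
    if log is not None:
        log.record("hit_filter", len(table), int(mask.sum()),
                   gene=gene or "", ceiling=ceiling)
    return table.loc[mask].reset_index(drop=True)


def check_key_residues(alignment: Union[Alignment, Mapping[str, str]],
                       spec: ResidueSpec) -> pd.Series:
    """Per-sequence pass/fail under the key-residue requirements.

    A sequence passes iff at every required column its character belongs to
    the allowed set; gaps never pass.  Raises if a column exceeds the
    alignment width.
    """
    if isinstance(alignment, Alignment):
        seqs = {label: alignment.sequence(label) for label in alignment.labels}
    else:
        seqs = dict(alignment)
    width = min((len(s) for s in seqs.values()), default=0)
    for col in spec.columns:
        if col > width:
            raise ValueError(
                f"residue spec column {col} beyond alignment width {width}"
            )
    verdict = {}
    for label, seq in seqs.items():
        ok = True
        for col, allowed in spec.columns.items():
            ch = seq[col - 1].upper()
            if ch in GAP_CHARACTERS or ch not in allowed:
                ok = False
                break
        verdict[label] = ok
    return pd.Series(verdict, name=f"{spec.gene}_key_residues", dtype=bool)


@dataclasses.dataclass
class AnnotationResult:
    retained: list[str]
    mismatched: list[str]
    unassigned: list[str]


def confirm_annotation(ids: Iterable[str], assignments: Mapping[str, str],
                       expected: str,
                       log: Optional[AttritionLog] = None) -> AnnotationResult:
    """Keep ids whose ortholog-group assignment equals ``expected``.

    Ids absent from the assignment table are removed and counted separately
    (they failed confirmation, not mismatched it).
    """
    retained, mismatched, unassigned = [], [], []
    ids = list(ids)
    for i in ids:
        if i not in assignments:
            unassigned.append(i)
        elif assignments[i] == expected:
            retained.append(i)
        else:
            mismatched.append(i)
    if log is not None:
        log.record("annotation", len(ids), len(retained),
                   expected=expected, unassigned=len(unassigned),
                   mismatched=len(mismatched))
    return AnnotationResult(retained, mismatched, unassigned)


def read_residue_spec(path, gene: Optional[str] = None) -> ResidueSpec:
    """Read a tab-separated residue spec: column_1based <tab> allowed residues.

    Lines starting with '#' are comments; the gene name may be given on a
    ``# gene:`` header line or via the ``gene`` argument.
    """
    columns: dict[int, frozenset[str]] = {}
    name = gene
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.lower().startswith("# gene:"):
                    name = line.split(":", 1)[1].strip()
                continue
            col_s, residues = line.split("\t")[:2]
            columns[int(col_s)] = frozenset(residues.strip().upper())
    return ResidueSpec(gene=name or "unknown", columns=columns)
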
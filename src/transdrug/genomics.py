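"""Binary genomic-alteration matrix from copy-number and variant calls.

Per gene, three binary features are emitted: amp<GENE> (more than two
copies of at least one allele), del<GENE> (at least one allele missing),
and var<GENE> (a retained deleterious nonsynonymous SNV). Synonymous SNVs
and nonsynonymous SNVs not predicted deleterious are filtered out; the
deleteriousness verdicts (SIFT / PolyPhen2 / FATHMM) arrive pre-tabulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CONSEQUENCES = ("synonymous", "nonsynonymous", "other")
VariantRule = Literal["any", "all"]


@dataclass(frozen=True)
class CopyNumberRecord:
    cell_line: str
    gene: str
    major_copies: int
    minor_copies: int

    def __post_init__(self) -> None:
        if self.major_copies < 0 or self.minor_copies < 0:
            raise ValueError("allele copies must be non-negative")


@dataclass(frozen=True)
class VariantRecord:
    cell_line: str
    gene: str
    consequence: str
    sift_deleterious: bool | None = None
    polyphen_deleterious: bool | None = None
    fathmm_deleterious: bool | None = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"consequence must be one of {CONSEQUENCES}")

    @property
    def verdicts(self) -> list[bool]:
        """Available (non-missing) predictor verdicts."""
        return [
            v
            for v in (self.sift_deleterious, self.polyphen_deleterious, self.fathmm_deleterious)
            if v is not None
        ]


def call_amplification(rec: CopyNumberRecord) -> bool:
    """More than two copies of at least one allele (strictly > 2)."""
    return max(rec.major_copies, rec.minor_copies) > 2


def call_deletion(rec: CopyNumberRecord) -> bool:
    """At least one allele missing entirely."""
    return min(rec.major_copies, rec.minor_copies) == 0


def filter_variant(rec: VariantRecord, rule: VariantRule = "any") -> bool:
    """Whether a variant is retained for the var<GENE> feature.

    Synonymous (and "other") variants are dropped. Nonsynonymous variants
    are kept iff the available predictor verdicts flag deleteriousness —
    under the default "any" rule a single deleterious verdict suffices;
    under "all", every available verdict must be deleterious. Missing
    verdicts are abstentions; a variant with no verdict at all is dropped.
    """
    if rec.consequence != "nonsynonymous":
        return False
    verdicts = rec.verdicts
    if not verdicts:
        return False
    return any(verdicts) if rule == "any" else all(verdicts)


def build_alteration_matrix(
    cn: Iterable[CopyNumberRecord],
    var: Iterable[VariantRecord],
    genes: Sequence[str],
    cell_lines: Sequence[str] | None = None,
    rule: VariantRule = "any",
) -> pd.DataFrame:
    """Cell-line x (amp/del/var per gene) binary matrix.

    An entry is 1 iff any record for that (line, gene) passes the
    corresponding call; lines or genes without records stay 0. Records for
    genes outside ``genes`` are ignored with a logged count.
    """
    cn = list(cn)
    var = list(var)
    gene_set = set(genes)
    if cell_lines is None:
        cell_lines = sorted({r.cell_line for r in cn} | {r.cell_line for r in var})
    cols = [f"{p}{g}" for g in genes for p in ("amp", "del", "var")]
    mat = pd.DataFrame(0, index=list(cell_lines), columns=cols, dtype="int8")

    ignored = 0
    for rec in cn:
        if rec.gene not in gene_set:
            ignored += 1
            continue
        if rec.cell_line not in mat.index:
            continue
        if call_amplification(rec):
            mat.loc[rec.cell_line, f"amp{rec.gene}"] = 1
        if call_deletion(rec):
            mat.loc[rec.cell_line, f"del{rec.gene}"] = 1
    for rec in var:
        if rec.gene not in gene_set:
            ignored += 1
            continue
        if rec.cell_line not in mat.index:
            continue
        if filter_variant(rec, rule):
            mat.loc[rec.cell_line, f"var{rec.gene}"] = 1
    if ignored:
        logger.info("ignored %d records for genes outside the panel list", ignored)
    return mat


# ---------------------------------------------------------------------------
# TSV interchange

_VERDICT = {"del": True, "tol": False, "NA": None, "": None}


def read_copy_number(path: str | Path) -> list[CopyNumberRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        CopyNumberRecord(r.cell_line, r.gene, int(r.major_copies), int(r.minor_copies))
        for r in df.itertuples()
    ]


def read_variants(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        VariantRecord(
            r.cell_line,
            r.gene,
            r.consequence,
            _VERDICT[r.sift],
            _VERDICT[r.polyphen],
            _VERDICT[r.fathmm],
        )
        for r in df.itertuples()
    ]


def write_alteration_matrix(mat: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    mat.rename_axis("cell_line").to_csv(path, sep="\t")
    return path
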
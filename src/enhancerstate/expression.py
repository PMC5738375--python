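"""Two-stage fold-change classification of induced genes and KO dependency.

Genes are first partitioned by the control-genotype fold change between the
start (D0) and mid-point (D2) of differentiation: up if fold >= cutoff
(default 2.5), down if fold <= 1/cutoff, else unchanged. Up-regulated genes
are then split into knockout-dependent and -independent by comparing the D2
expression between control (GFP) and knockout (Cre) cells at a second fold
cutoff (default 2.5). A small pseudocount guards zero-expression genes; all
cutoff comparisons are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic import IntervalSet, TssTable, ValidationError, nearest_genes

GENOTYPES = ("GFP", "Cre")
TIMEPOINTS = ("D0", "D2")
CONDITIONS = tuple(f"{g}_{t}" for g in GENOTYPES for t in TIMEPOINTS)

REGULATION = ("up", "down", "unchanged")
DEPENDENCY = ("dependent", "independent", "not_applicable")


@dataclass
class ExpressionTable:
    """Per-gene expression over genotype x timepoint conditions.

    values: DataFrame indexed by gene_id with columns GFP_D0, GFP_D2, Cre_D0,
    Cre_D2 (normalized units, e.g. per-million-scaled); all values >= 0.
    """

    values: pd.DataFrame
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")
        present = [c for c in CONDITIONS if c in self.values.columns]
        if not present:
            raise ValidationError(f"expression table has none of {CONDITIONS}")
        if (self.values[present] < 0).any().any():
            raise ValidationError("negative expression values")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene ids in expression table")

    def require(self, *cols: str) -> None:
        missing = [c for c in cols if c not in self.values.columns]
        if missing:
            raise ValidationError(f"expression table missing columns: {missing}")

    @classmethod
    def read_tsv(cls, path, pseudocount: float = 0.1) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(df, pseudocount=pseudocount)

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


def expressed_gene_filter(expr: ExpressionTable, floor: float) -> list[str]:
    """Genes whose maximum expression across conditions reaches `floor`.

    Defines the expressed-gene universe over which regulation classes are
    called (dataset-scale gene universes imply such a floor).
    """
    present = [c for c in CONDITIONS if c in expr.values.columns]
    keep = expr.values[present].max(axis=1) >= floor
    return list(expr.values.index[keep])


def classify_regulation(
    expr: ExpressionTable,
    cutoff: float = 2.5,
    control_genotype: str = "GFP",
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Up/down/unchanged calls from the control-genotype D2/D0 fold change.

    fold = (D2 + pseudocount) / (D0 + pseudocount); up if fold >= cutoff,
    down if fold <= 1/cutoff (inclusive boundaries).
    """
    if cutoff <= 1:
        raise ValidationError("cutoff must exceed 1")
    d0, d2 = f"{control_genotype}_D0", f"{control_genotype}_D2"
    expr.require(d0, d2)
    vals = expr.values if genes is None else expr.values.loc[genes]
    pc = expr.pseudocount
    fold = (vals[d2] + pc) / (vals[d0] + pc)
    regulation = np.where(fold >= cutoff, "up", np.where(fold <= 1 / cutoff, "down", "unchanged"))
    return pd.DataFrame({"fold_d2_d0": fold, "regulation": regulation}, index=vals.index)


def classify_dependency(
    expr: ExpressionTable,
    regulation: pd.DataFrame,
    cutoff: float = 2.5,
    mode: str = "ratio",
) -> pd.DataFrame:
    """KO-dependency calls for up-regulated genes.

    mode="ratio" (default): dependent if (GFP_D2 + pc) / (Cre_D2 + pc) >=
    cutoff — KO expression at D2 is at least cutoff-fold below control.
    mode="induction": dependent if the KO's own induction
    (Cre_D2 + pc) / (Cre_D0 + pc) stays below the cutoff — induction is lost
    in the knockout. Genes not called up are labeled not_applicable.
    """
    if cutoff <= 1:
        raise ValidationError("cutoff must exceed 1")
    if mode not in ("ratio", "induction"):
        raise ValidationError(f"unknown dependency mode {mode!r}")
    pc = expr.pseudocount
    vals = expr.values.loc[regulation.index]
    if mode == "ratio":
        expr.require("GFP_D2", "Cre_D2")
        fold = (vals["GFP_D2"] + pc) / (vals["Cre_D2"] + pc)
        dependent = fold >= cutoff
    else:
        expr.require("Cre_D0", "Cre_D2")
        fold = (vals["Cre_D2"] + pc) / (vals["Cre_D0"] + pc)
        dependent = fold < cutoff
    up = regulation["regulation"].to_numpy() == "up"
    dep = np.where(up, np.where(dependent, "dependent", "independent"), "not_applicable")
    out = regulation.copy()
    out["fold_gfp_cre"] = fold
    out["dependency"] = dep
    out["dependency_mode"] = mode
    return out


def regulation_summary(calls: pd.DataFrame) -> dict[str, int]:
    """Machine-readable class counts (partition identities hold)."""
    reg = calls["regulation"].value_counts()
    out = {f"n_{cls}": int(reg.get(cls, 0)) for cls in REGULATION}
    out["n_genes"] = int(len(calls))
    if "dependency" in calls.columns:
        dep = calls["dependency"].value_counts()
        out["n_dependent"] = int(dep.get("dependent", 0))
        out["n_independent"] = int(dep.get("independent", 0))
    return out


def link_peaks_to_dependency(
    regions: IntervalSet, tss: TssTable, calls: pd.DataFrame
) -> pd.DataFrame:
    """Label each region with its nearest gene's regulation/dependency.

    Regions on chromosomes without a TSS, or whose nearest gene has no call,
    are labeled not_applicable.
    """
    assigned = nearest_genes(regions, tss)
    regulation, dependency = [], []
    for gid in assigned["gene_id"]:
        if gid != "unassigned" and gid in calls.index:
            regulation.append(calls.loc[gid, "regulation"])
            dependency.append(
                calls.loc[gid, "dependency"] if "dependency" in calls.columns else "not_applicable"
            )
        else:
            regulation.append("not_applicable")
            dependency.append("not_applicable")
    assigned["regulation"] = regulation
    assigned["dependency"] = dependency
    return assigned
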
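"""Three-way DEG overlap and allele-dosage linear-response classification.

Genes significant (Bonferroni-adjusted p < alpha) in all three pairwise
contrasts — Het vs WT, NullA vs WT, NullB vs WT — form the overlap set.
An overlapping gene shows a *dosage effect* (genotype-dependent linear
response) when its Het-vs-WT change exceeds 2-fold and each Null clone
amplifies that change at least 1.5-fold further in the same direction:

    up:    fc_het > 2        and  fc_nullX / fc_het >= 1.5  (both clones)
    down:  fc_het < 1/2      and  fc_het / fc_nullX >= 1.5  (both clones)

Fold changes are linear-scale (fc = 2^log2fc; fc > 1 up, fc < 1 down).
The Het gate is strict ("more than 2-fold"); the amplification gate is
inclusive ("at least 1.5-fold").  Genes failing the rule but significant
in all three comparisons are reported as ``overlap_only``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de_testing import ComparisonResult
from .errors import DesignError, ValidationError

HET_FC_MIN = 2.0
AMPLIFICATION_MIN = 1.5

COMPARISON_IDS = ("HetVsWT", "NullAVsWT", "NullBVsWT")


@dataclass(frozen=True)
class OverlapSet:
    """Genes significant in all three contrasts, with linear fold changes."""

    genes: frozenset[str]
    per_gene_fc: pd.DataFrame  # index gene_id: fc_het, fc_nullA, fc_nullB
    n_overlap: int


@dataclass(frozen=True)
class DosageCallSet:
    """Dosage-effect calls for every overlap gene, plus summary counts."""

    table: pd.DataFrame  # gene_id, call, fc_het, fc_nullA, fc_nullB, amplification_A, amplification_B
    n_linear_up: int
    n_linear_down: int
    het_fc_min: float
    amplification_min: float

    @property
    def linear_genes(self) -> frozenset[str]:
        mask = self.table["call"].isin(["linear_up", "linear_down"])
        return frozenset(self.table.loc[mask, "gene_id"])

    def genes_with_call(self, call: str) -> list[str]:
        return self.table.loc[self.table["call"] == call, "gene_id"].tolist()


def overlap_degs(results: list[ComparisonResult]) -> OverlapSet:
    """Intersect the significant gene sets of the three pairwise contrasts.

    Overlap membership requires Bonferroni significance in all three
    comparisons; because tested rows only exist for detection-filtered
    genes, every overlap gene was analyzable in all three.  Fold changes
    are carried per comparison on the linear scale.
    """
    ids = [r.comparison_id for r in results]
    if len(set(ids)) != len(ids):
        raise DesignError(f"duplicate comparison_ids: {ids}")
    if set(ids) != set(COMPARISON_IDS):
        raise DesignError(f"expected comparisons {COMPARISON_IDS}, got {ids}")
    by_id = {r.comparison_id: r for r in results}
    common = (
        by_id["HetVsWT"].significant_genes
        & by_id["NullAVsWT"].significant_genes
        & by_id["NullBVsWT"].significant_genes
    )
    genes = sorted(common)
    fc = pd.DataFrame(
        {
            "fc_het": np.exp2(by_id["HetVsWT"].table.loc[genes, "log2fc"]),
            "fc_nullA": np.exp2(by_id["NullAVsWT"].table.loc[genes, "log2fc"]),
            "fc_nullB": np.exp2(by_id["NullBVsWT"].table.loc[genes, "log2fc"]),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return OverlapSet(genes=frozenset(genes), per_gene_fc=fc, n_overlap=len(genes))


def classify_dosage(
    fc_het: float,
    fc_nullA: float,
    fc_nullB: float,
    het_fc_min: float = HET_FC_MIN,
    amplification_min: float = AMPLIFICATION_MIN,
) -> tuple[str, float, float]:
    """Classify one gene's fold-change triplet by the dosage-effect rule.

    Returns (call, amplification_A, amplification_B) where the
    amplifications are fc_null/fc_het for up-genes and fc_het/fc_null for
    down-genes (so >= 1 means "further in the Het direction").
    """
    for name, fc in (("fc_het", fc_het), ("fc_nullA", fc_nullA), ("fc_nullB", fc_nullB)):
        if not (np.isfinite(fc) and fc > 0):
            raise ValidationError(f"{name} must be a finite positive fold change, got {fc}")
    up = fc_het > 1.0
    if up:
        amp_a, amp_b = fc_nullA / fc_het, fc_nullB / fc_het
        gate = fc_het > het_fc_min
        concordant = fc_nullA > 1.0 and fc_nullB > 1.0
    else:
        amp_a, amp_b = fc_het / fc_nullA, fc_het / fc_nullB
        gate = fc_het < 1.0 / het_fc_min
        concordant = fc_nullA < 1.0 and fc_nullB < 1.0
    if gate and concordant and amp_a >= amplification_min and amp_b >= amplification_min:
        call = "linear_up" if up else "linear_down"
    else:
        call = "overlap_only"
    return call, float(amp_a), float(amp_b)


def dosage_report(
    overlap: OverlapSet,
    het_fc_min: float = HET_FC_MIN,
    amplification_min: float = AMPLIFICATION_MIN,
) -> DosageCallSet:
    """Apply the dosage-effect rule to every overlap gene.

    Output rows are sorted: linear_up by descending Het fold change, then
    linear_down by ascending Het fold change, then overlap_only genes
    alphabetically.
    """
    rows = []
    for gene, r in overlap.per_gene_fc.iterrows():
        call, amp_a, amp_b = classify_dosage(
            r["fc_het"], r["fc_nullA"], r["fc_nullB"], het_fc_min, amplification_min
        )
        rows.append(
            {
                "gene_id": gene,
                "call": call,
                "fc_het": r["fc_het"],
                "fc_nullA": r["fc_nullA"],
                "fc_nullB": r["fc_nullB"],
                "amplification_A": amp_a,
                "amplification_B": amp_b,
            }
        )
    cols = [
        "gene_id", "call", "fc_het", "fc_nullA", "fc_nullB",
        "amplification_A", "amplification_B",
    ]
    df = pd.DataFrame(rows, columns=cols)
    up = df[df["call"] == "linear_up"].sort_values(
        ["fc_het", "gene_id"], ascending=[False, True]
    )
    down = df[df["call"] == "linear_down"].sort_values(["fc_het", "gene_id"])
    rest = df[df["call"] == "overlap_only"].sort_values("gene_id")
    out = pd.concat([up, down, rest], ignore_index=True)
    return DosageCallSet(
        table=out,
        n_linear_up=len(up),
        n_linear_down=len(down),
        het_fc_min=float(het_fc_min),
        amplification_min=float(amplification_min),
    )
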
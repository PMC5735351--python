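"""RPKM normalization, threshold-based DEG calling, and gene-set algebra.

The differential-expression caller follows the classic two-criterion rule:
a gene is UP in a contrast if its group-mean fold change (alt/ref, with a
pseudocount) exceeds fc_up AND a two-sided t-test p-value is at or below
p_max; DOWN symmetrically below fc_down. The default thresholds are
(1.50, 0.67, 0.05); a looser microarray preset (1.2, 0.83, 0.05) is
provided. The t-test runs on log2(RPKM + 1) by default (Welch variant),
with raw-scale and pooled-variance (Student) modes available since the
rule is often applied either way in the literature.
"""

from __future__ import annotations

import itertools
from collections.abc import Mapping
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, canonical_symbol

UP = "UP"
DOWN = "DOWN"
NS = "NS"
UNTESTABLE = "UNTESTABLE"


@dataclass
class ExpressionMatrix:
    """Gene x sample RPKM values with the sample -> group mapping."""

    rpkm: pd.DataFrame
    group_of: dict[str, str]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.rpkm.index)

    def samples_in_group(self, group: str) -> list[str]:
        found = [s for s in self.rpkm.columns if self.group_of.get(s) == group]
        if not found:
            raise ValueError(f"no samples in group {group!r}")
        return found


@dataclass(frozen=True)
class DEGThresholds:
    """Fold-change and p-value bounds plus the test configuration."""

    fc_up: float = 1.50
    fc_down: float = 0.67
    p_max: float = 0.05
    test: str = "welch"  # or "student"
    value_scale: str = "log2_pseudocount"  # or "raw"
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not self.fc_down < 1 < self.fc_up:
            raise ValueError("need fc_down < 1 < fc_up")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must lie in (0, 1]")
        if self.test not in ("welch", "student"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.value_scale not in ("log2_pseudocount", "raw"):
            raise ValueError(f"unknown value_scale {self.value_scale!r}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


THRESHOLD_PRESETS: dict[str, DEGThresholds] = {
    "gse61915": DEGThresholds(fc_up=1.50, fc_down=0.67, p_max=0.05),
    "gse75416": DEGThresholds(fc_up=1.2, fc_down=0.83, p_max=0.05),
}


@dataclass
class ContrastResult:
    """Per-gene fold change, p-value and status for one group contrast."""

    label: str
    table: pd.DataFrame  # columns: mean_ref, mean_alt, fold_change, p_value, status

    @property
    def up_genes(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["status"] == UP])

    @property
    def down_genes(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["status"] == DOWN])


def compute_rpkm(cm: CountMatrix) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    rpkm[g, s] = counts[g, s] * 1e9 / (length_bp[g] * library_size[s]),
    with the library size taken as the column sum of the count matrix.
    """
    lib = cm.counts.sum(axis=0)
    zero = lib.index[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {', '.join(zero)}")
    rpkm = (
        cm.counts.astype(float)
        .mul(1e9)
        .div(cm.gene_length_bp, axis=0)
        .div(lib, axis=1)
    )
    return ExpressionMatrix(rpkm=rpkm, group_of=dict(cm.group_of))


def call_degs(
    expr: ExpressionMatrix,
    ref_group: str,
    alt_group: str,
    thresholds: DEGThresholds | None = None,
    label: str | None = None,
) -> ContrastResult:
    """Call UP/DOWN genes for one contrast under the two-criterion rule.

    Genes that are all-zero across both groups are reported UNTESTABLE and
    excluded from testing, as are zero-variance genes with equal group
    means (the t statistic is undefined there). Both groups need at least
    two samples.
    """
    thresholds = thresholds or DEGThresholds()
    ref_samples = expr.samples_in_group(ref_group)
    alt_samples = expr.samples_in_group(alt_group)
    if len(ref_samples) < 2 or len(alt_samples) < 2:
        raise ValueError(
            f"t-test needs >= 2 samples per group "
            f"(got {len(ref_samples)} in {ref_group!r}, {len(alt_samples)} in {alt_group!r})"
        )

    ref = expr.rpkm[ref_samples].to_numpy(float)
    alt = expr.rpkm[alt_samples].to_numpy(float)
    mean_ref = ref.mean(axis=1)
    mean_alt = alt.mean(axis=1)
    pc = thresholds.pseudocount
    fc = (mean_alt + pc) / (mean_ref + pc)

    if thresholds.value_scale == "log2_pseudocount":
        ref_t, alt_t = np.log2(ref + 1.0), np.log2(alt + 1.0)
    else:
        ref_t, alt_t = ref, alt

    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pval = stats.ttest_ind(
            alt_t, ref_t, axis=1, equal_var=(thresholds.test == "student")
        )

    all_zero = (ref == 0).all(axis=1) & (alt == 0).all(axis=1)
    zero_var = (ref_t.std(axis=1) == 0) & (alt_t.std(axis=1) == 0)
    degenerate = zero_var & np.isclose(ref_t.mean(axis=1), alt_t.mean(axis=1))
    # zero variance but different means: the separation is infinite
    pval = np.where(zero_var & ~degenerate, 0.0, pval)

    status = np.full(len(fc), NS, dtype=object)
    tested = ~(all_zero | degenerate) & ~np.isnan(pval)
    status[tested & (fc >= thresholds.fc_up) & (pval <= thresholds.p_max)] = UP
    status[tested & (fc <= thresholds.fc_down) & (pval <= thresholds.p_max)] = DOWN
    status[all_zero | degenerate | np.isnan(pval)] = UNTESTABLE
    pval = np.where(status == UNTESTABLE, np.nan, pval)

    table = pd.DataFrame(
        {
            "mean_ref": mean_ref,
            "mean_alt": mean_alt,
            "fold_change": fc,
            "p_value": pval,
            "status": status,
        },
        index=expr.rpkm.index,
    )
    return ContrastResult(label=label or f"{alt_group}/{ref_group}", table=table)


# ---------------------------------------------------------------------------
# set algebra
# ---------------------------------------------------------------------------


@dataclass
class VennPartition:
    """Exact disjoint-region decomposition of 2-3 labeled gene sets."""

    labels: tuple[str, ...]
    regions: dict[frozenset[str], frozenset[str]]
    direction: str | None = None

    def region(self, *labels: str) -> frozenset[str]:
        """Elements in exactly these sets and no others."""
        return self.regions.get(frozenset(labels), frozenset())

    def intersection(self, *labels: str) -> frozenset[str]:
        """Elements in at least these sets (the classic Venn overlap count)."""
        want = frozenset(labels)
        out: set[str] = set()
        for key, members in self.regions.items():
            if want <= key:
                out |= members
        return frozenset(out)

    @property
    def union_size(self) -> int:
        return sum(len(m) for m in self.regions.values())


def venn_partition(
    sets: Mapping[str, Iterable[str]] | Iterable[tuple[str, Iterable[str]]],
    direction: str | None = None,
) -> VennPartition:
    """Decompose 2-3 labeled sets into their disjoint intersection regions.

    ``sets`` is a mapping label -> genes, or an iterable of (label, genes)
    pairs; duplicate labels are rejected.
    """
    if not isinstance(sets, Mapping):
        pairs = list(sets)
        labels = tuple(lab for lab, _ in pairs)
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate set labels")
        sets = dict(pairs)
    labels = tuple(sets)
    if not 2 <= len(labels) <= 3:
        raise ValueError("venn_partition supports 2 or 3 sets")
    as_sets = {lab: frozenset(sets[lab]) for lab in labels}
    regions: dict[frozenset[str], frozenset[str]] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = frozenset(combo)
            members = frozenset.intersection(*(as_sets[l] for l in combo))
            for other in labels:
                if other not in inside:
                    members -= as_sets[other]
            regions[inside] = members
    return VennPartition(labels=labels, regions=regions, direction=direction)


@dataclass(frozen=True)
class OverlapReport:
    """Cross-experiment comparison of two gene sets."""

    intersection: frozenset[str]
    jaccard: float
    p_hypergeometric: float | None = None

    @property
    def n_overlap(self) -> int:
        return len(self.intersection)


def compare_experiments(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str] | None = None,
) -> OverlapReport:
    """Overlap, Jaccard index, and (given a universe) the upper-tail
    hypergeometric probability of an overlap at least this large."""
    a = frozenset(canonical_symbol(g) for g in set_a)
    b = frozenset(canonical_symbol(g) for g in set_b)
    if not a or not b:
        raise ValueError("both gene sets must be non-empty")
    inter = a & b
    jaccard = len(inter) / len(a | b)
    p = None
    if universe is not None:
        u = frozenset(canonical_symbol(g) for g in universe)
        if not (a <= u and b <= u):
            offending = sorted((a | b) - u)[:5]
            raise ValueError(f"universe does not contain: {', '.join(offending)}")
        p = float(stats.hypergeom.sf(len(inter) - 1, len(u), len(a), len(b)))
    return OverlapReport(intersection=inter, jaccard=jaccard, p_hypergeometric=p)
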
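"""Scalar repertoire statistics and group-comparison wrappers.

Definitions (per sample, over clone sizes ``Clones_i`` ranked
descending, n unique clonotypes, Total_Clones = sum of cells):

* clonality = (sum of the top k = max(1, floor(0.1 n)) clone sizes)
  / Total_Clones — cumulative frequency of the top 10% of clones;
* diversity = Unique_Clones / Total_Clones, 1 for all-singletons;
* CEI (clonal expansion index) = mean of per-clonotype frequencies
  R_i; with R_i as proportions this is algebraically 1/N, with R_i as
  counts it is the mean clone size — both modes are exposed;
* expansion proportion: pre/post clonotype counts scaled so the two
  timepoints sum to 100%;
* tissue enrichment E = log2(T_pre / N_pre), positive when a subset
  prefers tumor over normal tissue at baseline;
* tumor response Delta = log2(T_post / T_pre), positive when a subset
  expands after treatment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class SampleMetrics:
    sample_id: str
    n_unique: int
    total_clones: int
    clonality: float
    diversity: float
    cei: float
    k_used: int


def clonality_score(clone_sizes, k_rule: str = "floor") -> tuple[float, int]:
    """Cumulative frequency of the top 10% of clones.

    k = max(1, floor(0.1 n)) by default (``k_rule='round'`` uses
    round-half-even instead).  Rank ties are harmless: any top-k choice
    sums identically.
    """
    sizes = sorted((int(s) for s in clone_sizes), reverse=True)
    if not sizes:
        raise ValueError("empty clone-size list")
    if sizes[-1] <= 0:
        raise ValueError("clone sizes must be positive")
    n = len(sizes)
    if k_rule == "floor":
        k = max(1, math.floor(0.1 * n))
    elif k_rule == "round":
        k = max(1, round(0.1 * n))
    else:
        raise ValueError(f"unknown k_rule {k_rule!r}")
    return sum(sizes[:k]) / sum(sizes), k


def diversity_score(n_unique: int, total_clones: int) -> float:
    """Unique_Clones / Total_Clones, in (0, 1]; 1 iff all singletons."""
    if total_clones <= 0 or n_unique <= 0:
        raise ValueError("counts must be positive")
    if n_unique > total_clones:
        raise ValueError("n_unique cannot exceed total_clones")
    return n_unique / total_clones


def clonal_expansion_index(frequencies, mode: str = "proportion") -> float:
    """Mean of per-clonotype frequencies R_i.

    In proportion mode the input must sum to 1, and the result is
    algebraically 1/N — a collapse that is a property of the printed
    definition, kept rather than "fixed".  In count mode the result is
    the mean clone size.
    """
    freqs = np.asarray(list(frequencies), dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency list")
    if mode == "proportion":
        if not math.isclose(freqs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("proportions must sum to 1")
    elif mode != "count":
        raise ValueError(f"unknown mode {mode!r}")
    return float(freqs.mean())


def expansion_proportion(pre_count: int, post_count: int) -> tuple[float, float]:
    """Percentages of clonotypes at each timepoint, summing to 100."""
    if pre_count < 0 or post_count < 0:
        raise ValueError("counts must be non-negative")
    total = pre_count + post_count
    if total == 0:
        raise ValueError("at least one timepoint must be non-zero")
    return 100.0 * pre_count / total, 100.0 * post_count / total


def _log2_ratio(num: float, den: float, pseudocount: float, what: str) -> float:
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    num_p = num + pseudocount
    den_p = den + pseudocount
    if num_p <= 0 or den_p <= 0:
        raise ValueError(
            f"{what} undefined for zero abundance without a positive pseudocount"
        )
    return math.log2(num_p / den_p)


def tissue_enrichment_score(t_pre: float, n_pre: float, pseudocount: float = 0.0) -> float:
    """E = log2(T_pre / N_pre): baseline tumor-vs-normal preference."""
    return _log2_ratio(t_pre, n_pre, pseudocount, "tissue enrichment score")


def tumor_response_score(t_pre: float, t_post: float, pseudocount: float = 0.0) -> float:
    """Delta = log2(T_post / T_pre): post-treatment expansion in tumor."""
    return _log2_ratio(t_post, t_pre, pseudocount, "tumor response score")


def delta_delta_table(proportions: pd.DataFrame) -> pd.DataFrame:
    """(post - pre proportion in tumor) - (post - pre in normal), per subset.

    ``proportions`` is tidy with columns subset, tissue (normal/tumor),
    timepoint (Pre/Post) and proportion.  Antisymmetric under swapping
    the tumor/normal labels.
    """
    required = {"subset", "tissue", "timepoint", "proportion"}
    if not required <= set(proportions.columns):
        raise ValueError(f"need columns {sorted(required)}")
    wide = proportions.pivot_table(
        index="subset", columns=["tissue", "timepoint"], values="proportion"
    )
    out = pd.DataFrame(index=wide.index)
    out["delta_tumor"] = wide[("tumor", "Post")] - wide[("tumor", "Pre")]
    out["delta_normal"] = wide[("normal", "Post")] - wide[("normal", "Pre")]
    out["delta_delta"] = out["delta_tumor"] - out["delta_normal"]
    return out


def compare_groups(values_a, values_b, test: str = "t_test") -> tuple[float, float]:
    """Two-sided two-sample comparison: Student's t or Mann-Whitney U."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if test == "t_test":
        if a.size < 2 or b.size < 2:
            raise ValueError("t-test needs >= 2 values per group")
        if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            raise ValueError("zero variance in both groups")
        stat, p = stats.ttest_ind(a, b)
    elif test == "wilcoxon":
        if a.size < 1 or b.size < 1:
            raise ValueError("need >= 1 value per group")
        # exact rank-sum null for small samples, asymptotic otherwise
        method = "exact" if max(a.size, b.size) <= 8 else "auto"
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(stat), float(p)


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(list(p_values), dtype=float), method="fdr_bh")[1]


def sample_metrics(table) -> pd.DataFrame:
    """Per-sample clonality / diversity / CEI from a RepertoireTable."""
    rows = []
    for sample_id in table.samples["sample_id"]:
        sizes = table.cells_in_sample(sample_id)
        sizes = sizes[sizes > 0]
        if sizes.empty:
            continue
        total = int(sizes.sum())
        clonality, k = clonality_score(sizes.tolist())
        rows.append(
            SampleMetrics(
                sample_id=sample_id,
                n_unique=int(len(sizes)),
                total_clones=total,
                clonality=clonality,
                diversity=diversity_score(len(sizes), total),
                cei=clonal_expansion_index((sizes / total).tolist(), "proportion"),
                k_used=k,
            ).__dict__
        )
    return pd.DataFrame(rows)
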
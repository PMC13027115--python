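"""Benchmark harness: match reconstructed chains against ground truth.

A query chain matches when the same cell carries a reference chain of
the same locus agreeing under the active mode — identical CDR3
nucleotides (strictest), identical CDR3 amino acids, or identical
amino acids plus the same allele-stripped V and J genes.  Each
reference chain is consumed at most once.  Rates:

* overlap vs reference = 100 * matched / n_reference
* overlap vs query     = 100 * matched / n_query
* recall  = 100 * identified reads / total original reads
* precision (per component) = 100 * true positives / identified

Reported percentages are rounded half-up to two decimals at the
reporting layer only; internal values stay unrounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .clonotypes import strip_allele

MATCH_MODES = ("junction_nt", "junction_aa", "gene_level")


def round2(value: float) -> float:
    """Round half-up to two decimals (reporting convention)."""
    return float(
        Decimal(repr(float(value))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


@dataclass
class BenchmarkResult:
    match_mode: str
    n_reference: int
    n_query: int
    n_matched: int
    overlap_vs_reference_pct: float
    overlap_vs_query_pct: float
    precision_v_pct: float | None = None
    precision_j_pct: float | None = None
    precision_d_pct: float | None = None
    precision_cdr3_pct: float | None = None

    def as_row(self) -> dict:
        row = {
            "match_mode": self.match_mode,
            "n_reference": self.n_reference,
            "n_query": self.n_query,
            "n_matched": self.n_matched,
            "overlap_vs_reference_pct": round2(self.overlap_vs_reference_pct),
            "overlap_vs_query_pct": round2(self.overlap_vs_query_pct),
        }
        for name in ("precision_v_pct", "precision_j_pct", "precision_d_pct", "precision_cdr3_pct"):
            value = getattr(self, name)
            row[name] = round2(value) if value is not None else None
        return row


def overlap_rates(n_reference: int, n_query: int, n_matched: int) -> tuple[float, float]:
    """(100*m/n_reference, 100*m/n_query), rounded to two decimals."""
    if n_reference <= 0 or n_query <= 0:
        raise ValueError("reference and query counts must be positive")
    if not 0 <= n_matched <= min(n_reference, n_query):
        raise ValueError("matched count inconsistent with set sizes")
    return (
        round2(100.0 * n_matched / n_reference),
        round2(100.0 * n_matched / n_query),
    )


def recall_rate(n_identified: int, n_total_reads: int) -> float:
    """100 * identified / total original reads, two decimals."""
    if n_total_reads <= 0:
        raise ValueError("total read count must be positive")
    if not 0 <= n_identified <= n_total_reads:
        raise ValueError("identified count out of range")
    return round2(100.0 * n_identified / n_total_reads)


def precision_rate(n_true_positive: int, n_identified: int) -> float:
    """100 * true positives / identified, two decimals.

    Implements positive predictive value TP / total-identified; the
    companion accuracy expression with TN in the denominator is not a
    precision and is deliberately not provided.
    """
    if n_identified <= 0:
        raise ValueError("identified count must be positive")
    if not 0 <= n_true_positive <= n_identified:
        raise ValueError("true-positive count out of range")
    return round2(100.0 * n_true_positive / n_identified)


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "cell_id" not in df.columns and "cell_barcode" in df.columns:
        df["cell_id"] = df["cell_barcode"]
    if "cdr3_nt" not in df.columns and "junction" in df.columns:
        df["cdr3_nt"] = df["junction"]
    if "cdr3_aa" not in df.columns and "junction_aa" in df.columns:
        df["cdr3_aa"] = df["junction_aa"]
    for col in ("cell_id", "locus"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    df["v_gene"] = df.get("v_call", pd.Series("", index=df.index)).map(strip_allele)
    df["j_gene"] = df.get("j_call", pd.Series("", index=df.index)).map(strip_allele)
    if "d_call" in df.columns:
        df["d_gene"] = df["d_call"].fillna("").map(strip_allele)
    else:
        df["d_gene"] = ""
    return df


def _match_key(mode: str) -> list[str]:
    if mode == "junction_nt":
        return ["cell_id", "locus", "cdr3_nt"]
    if mode == "junction_aa":
        return ["cell_id", "locus", "cdr3_aa"]
    if mode == "gene_level":
        return ["cell_id", "locus", "cdr3_aa", "v_gene", "j_gene"]
    raise ValueError(f"unknown match mode {mode!r}")


def match_contigs(
    query: pd.DataFrame, reference: pd.DataFrame, mode: str = "junction_nt"
) -> tuple[pd.DataFrame, int]:
    """Pair query chains with reference chains under the given mode.

    Equality classes are disjoint, so maximum bipartite matching
    reduces to pairing within each class: min(#query, #reference)
    pairs per class, each reference chain consumed at most once.
    Returns (paired records, n_matched).
    """
    q = _normalize(query)
    r = _normalize(reference)
    key = _match_key(mode)
    for df, name in ((q, "query"), (r, "reference")):
        if df["cell_id"].isna().any():
            raise ValueError(f"{name} records missing cell barcodes")
    pairs = []
    r_groups = {k: grp for k, grp in r.groupby(key)}
    for k, q_grp in q.groupby(key):
        r_grp = r_groups.get(k)
        if r_grp is None:
            continue
        m = min(len(q_grp), len(r_grp))
        q_sel = q_grp.head(m).reset_index(drop=True)
        r_sel = r_grp.head(m).reset_index(drop=True)
        pairs.append(
            pd.DataFrame(
                {
                    "cell_id": q_sel["cell_id"],
                    "locus": q_sel["locus"],
                    "q_v_gene": q_sel["v_gene"],
                    "r_v_gene": r_sel["v_gene"],
                    "q_v_call": q_sel.get("v_call", q_sel["v_gene"]),
                    "r_v_call": r_sel.get("v_call", r_sel["v_gene"]),
                    "q_j_gene": q_sel["j_gene"],
                    "r_j_gene": r_sel["j_gene"],
                    "q_d_gene": q_sel["d_gene"],
                    "r_d_gene": r_sel["d_gene"],
                    "q_cdr3_aa": q_sel.get("cdr3_aa", ""),
                    "r_cdr3_aa": r_sel.get("cdr3_aa", ""),
                }
            )
        )
    matched = (
        pd.concat(pairs, ignore_index=True)
        if pairs
        else pd.DataFrame(
            columns=[
                "cell_id", "locus", "q_v_gene", "r_v_gene", "q_v_call",
                "r_v_call", "q_j_gene", "r_j_gene", "q_d_gene", "r_d_gene",
                "q_cdr3_aa", "r_cdr3_aa",
            ]
        )
    )
    return matched, len(matched)


def benchmark(
    query: pd.DataFrame,
    reference: pd.DataFrame,
    modes: tuple[str, ...] = MATCH_MODES,
) -> list[BenchmarkResult]:
    """Full evaluation across match modes.

    Component precision counts a matched query chain as a true positive
    for V (respectively J, D) when its allele-stripped call equals the
    paired reference call; for CDR3 the match itself is the agreement.
    D precision is reported only when both paired records carry a D call.
    """
    results = []
    n_query = len(query)
    n_reference = len(reference)
    for mode in modes:
        matched, n_matched = match_contigs(query, reference, mode)
        if n_query > 0:
            v_tp = int((matched["q_v_gene"] == matched["r_v_gene"]).sum())
            j_tp = int((matched["q_j_gene"] == matched["r_j_gene"]).sum())
            has_d = matched[(matched["q_d_gene"] != "") & (matched["r_d_gene"] != "")]
            d_tp = int((has_d["q_d_gene"] == has_d["r_d_gene"]).sum())
            precision_v = 100.0 * v_tp / n_query
            precision_j = 100.0 * j_tp / n_query
            precision_cdr3 = 100.0 * n_matched / n_query
            precision_d = 100.0 * d_tp / len(has_d) if len(has_d) else None
        else:
            precision_v = precision_j = precision_cdr3 = precision_d = None
        results.append(
            BenchmarkResult(
                match_mode=mode,
                n_reference=n_reference,
                n_query=n_query,
                n_matched=n_matched,
                overlap_vs_reference_pct=100.0 * n_matched / n_reference
                if n_reference
                else 0.0,
                overlap_vs_query_pct=100.0 * n_matched / n_query if n_query else 0.0,
                precision_v_pct=precision_v,
                precision_j_pct=precision_j,
                precision_d_pct=precision_d,
                precision_cdr3_pct=precision_cdr3,
            )
        )
    return results


def benchmark_report(results: list[BenchmarkResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])
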
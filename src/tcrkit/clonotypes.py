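"""Clonotype calling and repertoire sharing architecture.

A clonotype is defined per chain as the combination of locus,
allele-stripped V gene and CDR3 amino-acid sequence.  Sharing classes
partition clonotypes by the patients that carry them: private (one
patient), intra-group shared (several patients, one group) and
inter-group shared (patients from both groups).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

SHARING_CLASSES = ("private", "intra_group", "inter_group")


def strip_allele(call: str) -> str:
    """``TRBV27*01`` -> ``TRBV27``."""
    return call.split("*")[0] if isinstance(call, str) else call


@dataclass
class RepertoireTable:
    """Clonotypes x samples with study metadata.

    ``records`` has one row per clonotype (index = clonotype_id) with
    locus, v_gene, j_gene, cdr3_aa, per-clonotype totals, the patient
    set and the sharing class.  ``counts`` is long-form
    (clonotype_id, sample_id, cells).  ``samples`` carries the sample
    sheet (sample_id, patient, group, tissue, timepoint).
    """

    records: pd.DataFrame
    counts: pd.DataFrame
    samples: pd.DataFrame

    def cells_in_sample(self, sample_id: str) -> pd.Series:
        sub = self.counts[self.counts["sample_id"] == sample_id]
        return sub.set_index("clonotype_id")["cells"]

    def validate(self) -> None:
        known = set(self.samples["sample_id"])
        used = set(self.counts["sample_id"])
        if not used <= known:
            raise ValueError(f"unknown sample ids in counts: {sorted(used - known)}")
        if (self.counts["cells"] < 0).any():
            raise ValueError("negative cell counts")


def call_clonotypes(
    annotations: pd.DataFrame, samples: pd.DataFrame
) -> RepertoireTable:
    """Aggregate productive chain annotations into a clonotype table.

    ``annotations`` needs columns sample_id, cell_id, locus, v_call,
    j_call, cdr3_aa (junction_aa accepted as an alias) and productive.
    A cell contributes one count per distinct (sample, clonotype key)
    regardless of read support; cells carrying two productive chains of
    the same locus contribute to both keys.
    """
    df = annotations.copy()
    if "cdr3_aa" not in df.columns and "junction_aa" in df.columns:
        df["cdr3_aa"] = df["junction_aa"]
    if "cell_id" not in df.columns and "cell_barcode" in df.columns:
        df["cell_id"] = df["cell_barcode"]
    required = {"sample_id", "cell_id", "locus", "v_call", "j_call", "cdr3_aa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotations missing columns: {sorted(missing)}")
    if "productive" in df.columns:
        df = df[df["productive"].astype(str).str.upper().isin(["T", "TRUE", "1"])]
    unknown = set(df["sample_id"]) - set(samples["sample_id"])
    if unknown:
        raise ValueError(f"sample ids missing from metadata: {sorted(unknown)}")

    df = df.assign(
        v_gene=df["v_call"].map(strip_allele), j_gene=df["j_call"].map(strip_allele)
    )
    # one contribution per cell per key
    df = df.drop_duplicates(["sample_id", "cell_id", "locus", "v_gene", "cdr3_aa"])

    key_cols = ["locus", "v_gene", "cdr3_aa"]
    counts = (
        df.groupby(key_cols + ["sample_id"], as_index=False)
        .agg(cells=("cell_id", "nunique"))
    )
    meta = samples.set_index("sample_id")
    counts["patient"] = counts["sample_id"].map(meta["patient"])

    keys = counts[key_cols].drop_duplicates().sort_values(key_cols).reset_index(drop=True)
    keys["clonotype_id"] = [f"ct{i + 1:05d}" for i in range(len(keys))]
    counts = counts.merge(keys, on=key_cols)

    j_mode = (
        df.groupby(key_cols)["j_gene"]
        .agg(lambda s: Counter(s).most_common(1)[0][0])
        .rename("j_gene")
    )
    records = keys.set_index("clonotype_id").join(j_mode, on=key_cols)
    agg = counts.groupby("clonotype_id").agg(
        total_cells=("cells", "sum"),
        patients=("patient", lambda s: tuple(sorted(set(s)))),
    )
    records = records.join(agg)
    records["n_patients"] = records["patients"].map(len)
    records["sharing_class"] = pd.NA

    table = RepertoireTable(
        records=records,
        counts=counts[["clonotype_id", "sample_id", "cells"]].reset_index(drop=True),
        samples=samples.reset_index(drop=True),
    )
    table.validate()
    return table


def classify_sharing(
    table: RepertoireTable, group_map: dict[str, str] | None = None
) -> RepertoireTable:
    """Assign private / intra_group / inter_group to every clonotype."""
    if group_map is None:
        group_map = dict(zip(table.samples["patient"], table.samples["group"]))
    classes = []
    for patients in table.records["patients"]:
        unmapped = [p for p in patients if p not in group_map]
        if unmapped:
            raise ValueError(f"patients missing from group map: {unmapped}")
        if len(patients) == 1:
            classes.append("private")
        elif len({group_map[p] for p in patients}) == 1:
            classes.append("intra_group")
        else:
            classes.append("inter_group")
    table.records = table.records.assign(sharing_class=classes)
    return table


def sharing_summary(table: RepertoireTable) -> pd.Series:
    """Clonotype counts per sharing class (always all three classes)."""
    counts = table.records["sharing_class"].value_counts()
    return pd.Series(
        {cls: int(counts.get(cls, 0)) for cls in SHARING_CLASSES}, name="clonotypes"
    )


def cdr3_length_distribution(cdr3_aa: pd.Series | list[str]) -> tuple[dict[int, int], int]:
    """Histogram of CDR3 amino-acid lengths plus the modal length.

    Ties at the mode break to the smaller length.
    """
    seqs = list(cdr3_aa)
    if not seqs:
        raise ValueError("empty selection")
    hist = Counter(len(s) for s in seqs)
    max_count = max(hist.values())
    mode = min(length for length, c in hist.items() if c == max_count)
    return dict(sorted(hist.items())), mode


def positional_frequency_matrix(
    cdr3_set: list[str],
) -> tuple[pd.DataFrame, np.ndarray]:
    """Position-specific residue frequencies and information content.

    All sequences must share one length L.  Returns an L x 20 frequency
    matrix (rows sum to 1) and the per-position information content
    IC_j = log2(20) - H_j in bits, with no small-sample correction —
    the quantity a sequence logo displays.
    """
    if not cdr3_set:
        raise ValueError("empty selection")
    lengths = {len(s) for s in cdr3_set}
    if len(lengths) != 1:
        raise ValueError(f"mixed CDR3 lengths: {sorted(lengths)}")
    length = lengths.pop()
    if length < 1:
        raise ValueError("zero-length sequences")
    freq = np.zeros((length, len(AA_ALPHABET)))
    index = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    for seq in cdr3_set:
        for pos, aa in enumerate(seq):
            if aa not in index:
                raise ValueError(f"non-standard residue {aa!r}")
            freq[pos, index[aa]] += 1
    freq /= len(cdr3_set)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = math.log2(len(AA_ALPHABET)) - entropy
    matrix = pd.DataFrame(freq, columns=list(AA_ALPHABET))
    matrix.index.name = "position"
    return matrix, ic


def vj_pairing_matrix(
    records: pd.DataFrame, top_n: int | None = None
) -> pd.DataFrame:
    """Counts over (v_gene, j_gene) pairs, optionally restricted to the
    top_n most frequent V genes; rows ordered count desc then lexicographic."""
    if records.empty:
        return pd.DataFrame(columns=["v_gene", "j_gene", "count"])
    df = records[["v_gene", "j_gene"]].copy()
    if top_n is not None:
        v_counts = df["v_gene"].value_counts()
        ranked = sorted(v_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        keep = {v for v, _ in ranked[:top_n]}
        df = df[df["v_gene"].isin(keep)]
    pairs = df.groupby(["v_gene", "j_gene"], as_index=False).size()
    pairs = pairs.rename(columns={"size": "count"})
    return pairs.sort_values(
        ["count", "v_gene", "j_gene"], ascending=[False, True, True]
    ).reset_index(drop=True)


def select_top_shared(
    table: RepertoireTable, n: int = 50, scope: str = "all"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank clonotypes by how many patients carry them.

    ``scope='normal_tumor_shared'`` keeps only clonotypes with >= 1
    cell in a normal-tissue sample and >= 1 cell in a tumor sample.
    Rank: patient count desc, total cells desc, then cdr3_aa; the first
    n survive.  Also returns per-(group, tissue) patient counts for
    each selected clonotype — the edge weights a Sankey rendering of
    clone flow between tissues needs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    meta = table.samples.set_index("sample_id")
    counts = table.counts.assign(
        tissue=table.counts["sample_id"].map(meta["tissue"]),
        group=table.counts["sample_id"].map(meta["group"]),
        patient=table.counts["sample_id"].map(meta["patient"]),
    )
    counts = counts[counts["cells"] > 0]
    records = table.records
    if scope == "normal_tumor_shared":
        tissues = counts.groupby("clonotype_id")["tissue"].agg(set)
        keep = tissues[tissues.map(lambda t: "normal" in t and "tumor" in t)].index
        records = records.loc[records.index.isin(keep)]
    elif scope != "all":
        raise ValueError(f"unknown scope {scope!r}")
    ranked = records.sort_values(
        ["n_patients", "total_cells", "cdr3_aa"], ascending=[False, False, True]
    ).head(n)
    edges = (
        counts[counts["clonotype_id"].isin(ranked.index)]
        .groupby(["clonotype_id", "group", "tissue"], as_index=False)
        .agg(patients=("patient", "nunique"), cells=("cells", "sum"))
    )
    return ranked, edges


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_repertoire(table: RepertoireTable, records_path, counts_path, samples_path) -> None:
    out = table.records.reset_index()
    out["patients"] = out["patients"].map(lambda t: ",".join(t))
    out.to_csv(records_path, sep="\t", index=False)
    table.counts.to_csv(counts_path, sep="\t", index=False)
    table.samples.to_csv(samples_path, sep="\t", index=False)


def read_repertoire(records_path, counts_path, samples_path) -> RepertoireTable:
    records = pd.read_csv(records_path, sep="\t").set_index("clonotype_id")
    records["patients"] = records["patients"].map(lambda s: tuple(str(s).split(",")))
    counts = pd.read_csv(counts_path, sep="\t")
    samples = pd.read_csv(samples_path, sep="\t")
    table = RepertoireTable(records=records, counts=counts, samples=samples)
    table.validate()
    return table
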
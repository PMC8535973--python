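"""Mutation and copy-number summaries: per-gene mutation frequency,
pairwise co-mutation tests, CNV gain/loss frequency and per-sample
tumor mutation burden (raw nonsilent count; comparisons downstream are
rank-based so no per-megabase normalization is applied)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

VARIANT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Translation_Start_Site",
        "Silent",
    }
)
NONSILENT_CLASSES = frozenset(VARIANT_CLASSES - {"Silent"})


@dataclass
class MutationTable:
    """MAF-like records: one row per variant call.

    Columns: ``sample_id``, ``gene``, ``variant_classification``.  The same
    (sample, gene, class) triple may repeat (multiple variants).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        required = {"sample_id", "gene", "variant_classification"}
        if not required <= set(df.columns):
            raise ValueError(f"mutation table needs columns {sorted(required)}")
        bad = set(df["variant_classification"]) - VARIANT_CLASSES
        if bad:
            raise ValueError(f"unknown variant classification(s): {sorted(bad)[:10]}")
        self.records = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(set(self.records["sample_id"].astype(str)))


@dataclass
class CNVCalls:
    """Per-(sample, gene) integer copy-number states in {-2, -1, 0, 1, 2}."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        required = {"sample_id", "gene", "state"}
        if not required <= set(df.columns):
            raise ValueError(f"CNV table needs columns {sorted(required)}")
        states = df["state"].to_numpy()
        if not np.isin(states, (-2, -1, 0, 1, 2)).all():
            bad = sorted(set(states) - {-2, -1, 0, 1, 2})
            raise ValueError(f"CNV states outside {{-2..2}}: {bad[:10]}")
        self.records = df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def _nonsilent(t: MutationTable) -> pd.DataFrame:
    df = t.records
    return df[df["variant_classification"].isin(NONSILENT_CLASSES)]


def mutation_summary(
    t: MutationTable, panel: list[str], n_samples: int
) -> tuple[pd.DataFrame, float]:
    """Per-gene nonsilent mutation frequency over a panel, plus the overall
    fraction of samples altered in any panel gene.

    Returns a frame (gene, mutated_samples, freq) sorted by frequency
    descending (ties alphabetical) and the overall altered fraction.
    """
    observed = set(t.records["sample_id"])
    if n_samples < len(observed):
        raise ValueError(
            f"n_samples={n_samples} < {len(observed)} distinct samples in table"
        )
    ns = _nonsilent(t)
    per_gene: dict[str, set[str]] = {g: set() for g in panel}
    for g, sub in ns.groupby("gene"):
        if g in per_gene:
            per_gene[g] = set(sub["sample_id"])
    rows = [
        {"gene": g, "mutated_samples": len(s), "freq": len(s) / n_samples}
        for g, s in per_gene.items()
    ]
    out = pd.DataFrame(rows).sort_values(
        ["freq", "gene"], ascending=[False, True], ignore_index=True
    )
    altered: set[str] = set().union(*per_gene.values()) if per_gene else set()
    return out, len(altered) / n_samples


def comutation_test(
    t: MutationTable, gene_a: str, gene_b: str, n_samples: int
) -> tuple[float, float]:
    """Fisher exact test of sample-level co-mutation of two genes.

    Returns (odds_ratio, two-sided p).  The odds ratio uses the Haldane
    0.5 correction whenever a cell of the 2x2 table is zero.
    """
    observed = set(t.records["sample_id"])
    if n_samples < len(observed):
        raise ValueError("n_samples smaller than observed distinct samples")
    ns = _nonsilent(t)
    in_a = set(ns.loc[ns["gene"] == gene_a, "sample_id"])
    in_b = set(ns.loc[ns["gene"] == gene_b, "sample_id"])
    for g, hits in ((gene_a, in_a), (gene_b, in_b)):
        if not hits:
            warnings.warn(f"gene {g!r} never mutated; treated as all-wild")
    a = len(in_a & in_b)
    b = len(in_a - in_b)
    c = len(in_b - in_a)
    d = n_samples - len(in_a | in_b)
    table = np.array([[a, b], [c, d]], dtype=float)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if (table == 0).any():
        table = table + 0.5
    odds_ratio = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    return float(odds_ratio), float(p)


def cnv_frequency(c: CNVCalls, panel: list[str]) -> pd.DataFrame:
    """Gain/loss frequency per panel gene with a dominant-direction call.

    Frequencies are over the distinct samples present in the call table;
    genes without records get 0/0 and are 'balanced'.
    """
    df = c.records
    samples = sorted(set(df["sample_id"]))
    n = len(samples)
    rows = []
    for g in panel:
        sub = df[df["gene"] == g]
        gain = sub.loc[sub["state"] > 0, "sample_id"].nunique()
        loss = sub.loc[sub["state"] < 0, "sample_id"].nunique()
        gain_freq = gain / n if n else 0.0
        loss_freq = loss / n if n else 0.0
        if gain_freq > loss_freq:
            dominant = "amplification"
        elif loss_freq > gain_freq:
            dominant = "deletion"
        else:
            dominant = "balanced"
        rows.append(
            {
                "gene": g,
                "gain_freq": gain_freq,
                "loss_freq": loss_freq,
                "dominant": dominant,
            }
        )
    return pd.DataFrame(rows)


def tmb(t: MutationTable, sample_ids: list[str] | None = None) -> pd.Series:
    """Per-sample nonsilent variant count.

    ``sample_ids`` extends the result to samples absent from the table
    (count 0).  Counts records, not distinct genes: a sample with two
    missense calls in one gene has burden 2.
    """
    ns = _nonsilent(t)
    counts = ns.groupby("sample_id").size()
    if sample_ids is not None:
        counts = counts.reindex(sample_ids, fill_value=0)
    return counts.astype(int).rename("tmb")


# ---------------------------------------------------------------------------
# readers (text TSV, MAF-style column names accepted)
# ---------------------------------------------------------------------------

_MAF_ALIASES = {
    "Tumor_Sample_Barcode": "sample_id",
    "Hugo_Symbol": "gene",
    "Variant_Classification": "variant_classification",
}


def read_mutations(path) -> MutationTable:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns=_MAF_ALIASES)
    df["sample_id"] = df["sample_id"].astype(str)
    df["gene"] = df["gene"].astype(str)
    return MutationTable(df[["sample_id", "gene", "variant_classification"]])


def read_cnv(path) -> CNVCalls:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"sample": "sample_id"})
    df["sample_id"] = df["sample_id"].astype(str)
    df["gene"] = df["gene"].astype(str)
    df["state"] = df["state"].astype(int)
    return CNVCalls(df[["sample_id", "gene", "state"]])
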
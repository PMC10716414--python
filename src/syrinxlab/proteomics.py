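"""Label-free proteome quantification from peptide LC peak tables.

Protein abundance is proxied by top-3 quantification: the sum of a
protein's three largest peptide LC peak areas (all areas when fewer
than three peptides were observed). Before quantification, peptides of
known red-blood-cell contaminant proteins are excluded, and peptides
shared across the fast/developmental myosin-heavy-chain cluster are
pooled into a single "MYH-fast" pseudo-protein (MYH13 stays separate,
being identifiable by unique peptides). Abundances are normalized both
to the total sum of peaks (compositional, rel_total) and to Histone H4
(a stable nuclear reference, rel_h4). Differential abundance between
paired intact/treated samples is tested on log2 ratios.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RBC_ACCESSIONS",
    "H4_ACCESSION",
    "MYH_FAST_NAME",
    "quantify_and_normalize",
    "differential_abundance",
    "category_rollup",
]

#: UniProt accessions of red-blood-cell proteins excluded as contamination.
RBC_ACCESSIONS = frozenset(
    {"A0A674HE74", "B5FXM1", "B5G3P7", "H0ZSY4", "A0A674HG19"}
)

#: UniProt accession of zebra finch Histone H4, the reference protein.
H4_ACCESSION = "B5FXC8"

#: Name given to the pooled fast/developmental MyHC cluster.
MYH_FAST_NAME = "MYH-fast"

CATEGORIES = ("sarcomeric", "ca_handling", "mitochondrial", "other")


def quantify_and_normalize(
    table: pd.DataFrame,
    category_map: Mapping[str, str] | None = None,
    exclusions: frozenset[str] | set[str] = RBC_ACCESSIONS,
    h4_accession: str = H4_ACCESSION,
    pool_myh_fast: bool = True,
    include_h4_in_total: bool = True,
) -> pd.DataFrame:
    """Top-3 quantification and normalization for one sample.

    Parameters
    ----------
    table : DataFrame
        Columns ``accession, gene, peptide, area`` and optionally
        ``myh_fast_cluster`` (boolean: peptide belongs to the shared
        fast-MyHC pool) and ``sample``.
    category_map : mapping accession -> category
        Unmapped proteins fall into "other".

    Returns a DataFrame with one row per protein: ``protein, gene,
    category, raw_top3, rel_total, rel_h4``. ``rel_total`` sums to 1
    over the included proteins; ``rel_h4`` is 1 for Histone H4 and NaN
    everywhere (with a warning) when H4 was not observed.
    """
    if len(table) == 0:
        raise ValueError("empty peptide table")
    df = table.copy()
    if "myh_fast_cluster" not in df.columns:
        df["myh_fast_cluster"] = False
    df["myh_fast_cluster"] = df["myh_fast_cluster"].fillna(False).astype(bool)
    # exclusion is exact set membership on accessions, never substring
    df = df[~df["accession"].isin(set(exclusions))]
    if len(df) == 0:
        raise ValueError("no peptides left after exclusion")
    df = df.drop_duplicates(subset=[c for c in ("accession", "peptide", "sample")
                                    if c in df.columns])
    pooled_key = np.where(df["myh_fast_cluster"] & pool_myh_fast,
                          MYH_FAST_NAME, df["accession"])
    df = df.assign(protein=pooled_key)

    top3 = (
        df.groupby("protein")["area"]
        .apply(lambda a: float(a.nlargest(3).sum()))
        .rename("raw_top3")
        .reset_index()
    )
    genes = (
        df.groupby("protein")["gene"].first().reset_index()
        if "gene" in df.columns else None
    )
    out = top3 if genes is None else top3.merge(genes, on="protein")

    total = out["raw_top3"].sum()
    if include_h4_in_total:
        out["rel_total"] = out["raw_top3"] / total
    else:
        denom = out.loc[out["protein"] != h4_accession, "raw_top3"].sum()
        out["rel_total"] = out["raw_top3"] / denom

    h4 = out.loc[out["protein"] == h4_accession, "raw_top3"]
    if len(h4):
        out["rel_h4"] = out["raw_top3"] / float(h4.iloc[0])
    else:
        warnings.warn("Histone H4 not found; rel_h4 omitted")
        out["rel_h4"] = np.nan

    cmap = dict(category_map or {})
    out["category"] = out["protein"].map(cmap).fillna("other")
    return out.sort_values("raw_top3", ascending=False).reset_index(drop=True)


def differential_abundance(
    intact: Sequence[pd.DataFrame],
    treated: Sequence[pd.DataFrame],
    abundance: str = "rel_h4",
    test: str = "paired",
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-protein differential abundance between paired sample sets.

    ``intact[i]`` and ``treated[i]`` are quantification outputs for the
    same animal. The fold change per protein is the geometric mean of
    per-pair treated/intact ratios of the chosen abundance column
    (default ``rel_h4``: ratio-to-reference normalization preserves
    per-protein fold changes, whereas the compositional ``rel_total``
    distorts them for dominant proteins). The test is a paired
    two-sided t-test on per-pair log2 ratios; ``test="welch"`` runs an
    unpaired Welch alternative on the log2 abundances. Proteins absent
    from any sample get a NaN fold change and are excluded from tests.
    Columns ``log2fc`` and ``neg_log10_p`` form the volcano table.
    """
    if len(intact) != len(treated) or len(intact) < 2:
        raise ValueError("need >= 2 paired samples")
    if test not in ("paired", "welch"):
        raise ValueError("test must be 'paired' or 'welch'")

    def pivot(profiles: Sequence[pd.DataFrame]) -> pd.DataFrame:
        return pd.concat(
            [p.set_index("protein")[abundance].rename(i)
             for i, p in enumerate(profiles)], axis=1
        )

    a = pivot(intact)
    b = pivot(treated)
    proteins = a.index.union(b.index)
    a = a.reindex(proteins)
    b = b.reindex(proteins)
    cats = pd.concat(intact + list(treated)).drop_duplicates("protein") \
        .set_index("protein")["category"].reindex(proteins).fillna("other")

    rows = []
    for prot in proteins:
        x = a.loc[prot].to_numpy(float)
        y = b.loc[prot].to_numpy(float)
        complete = np.all(np.isfinite(x)) and np.all(np.isfinite(y)) \
            and np.all(x > 0) and np.all(y > 0)
        if not complete:
            rows.append({"protein": prot, "category": cats[prot],
                         "mean_ratio": np.nan, "log2fc": np.nan,
                         "t": np.nan, "p": np.nan})
            continue
        log2r = np.log2(y) - np.log2(x)
        log2fc = float(np.mean(log2r))
        if test == "paired":
            if np.ptp(log2r) == 0:  # zero variance: degenerate t
                t = 0.0 if log2r[0] == 0 else np.sign(log2r[0]) * np.inf
                p = 1.0 if log2r[0] == 0 else 0.0
            else:
                t, p = stats.ttest_1samp(log2r, 0.0)
        else:
            t, p = stats.ttest_ind(np.log2(y), np.log2(x), equal_var=False)
        rows.append({"protein": prot, "category": cats[prot],
                     "mean_ratio": float(2.0**log2fc), "log2fc": log2fc,
                     "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    if bh_correction:
        tested = out["p"].notna()
        out.loc[tested, "p_adj"] = stats.false_discovery_control(
            out.loc[tested, "p"].to_numpy()
        )
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p"])
    return out


def category_rollup(
    profiles: Sequence[pd.DataFrame], labels: Sequence[str] | None = None,
    abundance: str = "rel_total",
) -> pd.DataFrame:
    """Summed relative abundance per category for each sample."""
    labels = list(labels) if labels is not None else list(range(len(profiles)))
    rows = []
    for lab, p in zip(labels, profiles):
        sums = p.groupby("category")[abundance].sum()
        for cat in CATEGORIES:
            rows.append({"sample": lab, "category": cat,
                         "summed_abundance": float(sums.get(cat, 0.0))})
    return pd.DataFrame(rows)
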
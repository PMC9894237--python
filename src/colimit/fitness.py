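"""Barcode-competition fitness statistics for pooled transposon libraries.

A barcoded transposon library is grown competitively; barcodes are counted
by sequencing at the start (T0) and after several doublings in each
condition.  The fitness of a mutant strain is the log2 ratio of its
*relative* abundance at the endpoint over the T0:

    fitness = log2( (n_end + p) / N_end ) - log2( (n_t0 + p) / N_t0 )

where N is the sample's total read count and p a small pseudocount.  A
value of -2 means a fourfold drop in relative abundance.  Gene-level
fitness averages the strains inserted in that gene (each insertion is an
internal biological replicate), after excluding strains too poorly
sampled at T0 to be informative.

Input tables are tidy (poolcount-style): one row per barcode x sample with
columns ``barcode``, ``gene``, ``sample``, ``count`` (``scaffold`` and
``pos`` are carried through when present).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "strain_fitness",
    "strain_fitness_table",
    "gene_fitness",
    "replicate_concordance",
    "summarize_gene_fitness",
    "read_counts",
]

REQUIRED_COLUMNS = ("barcode", "gene", "sample", "count")


def strain_fitness(n_end, n_t0, total_end: float, total_t0: float, pseudocount: float = 0.5):
    """log2 relative-abundance ratio of a strain (vectorized over counts).

    Abundances are compositional (count / sample total), so the statistic
    is invariant to sequencing depth; the pseudocount regularizes zero
    counts.  Raises if either sample total is nonpositive.
    """
    if total_end <= 0 or total_t0 <= 0:
        raise ValueError("sample totals must be positive read counts")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    n_end = np.asarray(n_end, dtype=float)
    n_t0 = np.asarray(n_t0, dtype=float)
    if np.any(n_end < 0) or np.any(n_t0 < 0):
        raise ValueError("counts must be nonnegative")
    f_end = (n_end + pseudocount) / total_end
    f_t0 = (n_t0 + pseudocount) / total_t0
    return np.log2(f_end / f_t0)


def _validate(counts: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    if (counts["count"] < 0).any():
        raise ValueError("counts must be nonnegative")
    genes_per_barcode = counts.groupby("barcode")["gene"].nunique()
    bad = genes_per_barcode[genes_per_barcode > 1]
    if len(bad):
        raise ValueError(f"barcodes mapping to >1 gene: {list(bad.index[:5])}")


def strain_fitness_table(
    counts: pd.DataFrame,
    t0_map: dict[str, str] | str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-strain fitness for every experimental sample in a count table.

    Parameters
    ----------
    counts : DataFrame
        Tidy counts with columns ``barcode, gene, sample, count``.
    t0_map : dict or str
        Mapping from experimental sample name to its T0 reference sample;
        a single string names one shared T0 for all other samples.
    pseudocount : float
        Reads added to each count before forming relative abundances.

    Returns
    -------
    DataFrame with one row per barcode x experimental sample:
    ``barcode, gene, sample, n_t0, n_end, fitness``.
    """
    _validate(counts)
    samples = list(counts["sample"].unique())
    if isinstance(t0_map, str):
        if t0_map not in samples:
            raise ValueError(f"T0 sample {t0_map!r} not present in table")
        t0_map = {s: t0_map for s in samples if s != t0_map}
    wide = (
        counts.pivot_table(
            index=["barcode", "gene"],
            columns="sample",
            values="count",
            aggfunc="sum",
            fill_value=0,
        )
        .reset_index()
    )
    totals = counts.groupby("sample")["count"].sum()
    out = []
    for sample, t0 in t0_map.items():
        for name in (sample, t0):
            if name not in wide.columns:
                raise ValueError(f"sample {name!r} not present in table")
        if totals[sample] == 0 and totals[t0] == 0:
            raise ValueError(f"samples {sample!r} and {t0!r} both have zero reads")
        fit = strain_fitness(
            wide[sample].to_numpy(),
            wide[t0].to_numpy(),
            float(totals[sample]),
            float(totals[t0]),
            pseudocount,
        )
        out.append(
            pd.DataFrame(
                {
                    "barcode": wide["barcode"],
                    "gene": wide["gene"],
                    "sample": sample,
                    "n_t0": wide[t0].to_numpy(),
                    "n_end": wide[sample].to_numpy(),
                    "fitness": fit,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def gene_fitness(
    strain_table: pd.DataFrame,
    min_t0_reads: int = 3,
    weighted: bool = False,
) -> pd.DataFrame:
    """Aggregate strain fitness to genes (per sample).

    Strains with fewer than ``min_t0_reads`` T0 reads are excluded.  The
    default aggregate is the unweighted mean over passing insertion
    strains; ``weighted=True`` uses inverse-variance weights from the
    Poisson counting noise of the two counts.  Genes whose strains all
    fail the T0 filter are kept with ``fitness = NaN`` and
    ``flagged = True`` rather than silently dropped.
    """
    passing = strain_table[strain_table["n_t0"] >= min_t0_reads]

    def agg(group: pd.DataFrame) -> float:
        if not weighted:
            return float(group["fitness"].mean())
        w = 1.0 / (1.0 / (group["n_end"] + 0.5) + 1.0 / (group["n_t0"] + 0.5))
        return float(np.average(group["fitness"], weights=w))

    rows = []
    for (sample, gene), group in strain_table.groupby(["sample", "gene"], sort=True):
        ok = group[group["n_t0"] >= min_t0_reads]
        rows.append(
            {
                "sample": sample,
                "gene": gene,
                "n_strains": len(ok),
                "n_strains_total": len(group),
                "fitness": agg(ok) if len(ok) else np.nan,
                "flagged": len(ok) == 0,
            }
        )
    del passing
    return pd.DataFrame(rows)


def replicate_concordance(rep_a: pd.DataFrame, rep_b: pd.DataFrame) -> float:
    """Pearson correlation of gene-level fitness between two replicates.

    Inputs are gene-fitness tables (columns ``gene`` and ``fitness``);
    only genes present and unflagged in both are used, and at least three
    shared genes are required.
    """
    a = rep_a.dropna(subset=["fitness"]).set_index("gene")["fitness"]
    b = rep_b.dropna(subset=["fitness"]).set_index("gene")["fitness"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    r, _ = stats.pearsonr(a.loc[shared], b.loc[shared])
    return float(r)


def summarize_gene_fitness(gene_table: pd.DataFrame) -> dict:
    """Distribution summary (count, mean, quartiles/IQR) of gene fitness."""
    vals = gene_table["fitness"].dropna()
    q1, med, q3 = (float(vals.quantile(q)) for q in (0.25, 0.5, 0.75)) if len(vals) else (
        np.nan,
        np.nan,
        np.nan,
    )
    return {
        "n_genes": int(len(vals)),
        "n_flagged": int(gene_table["flagged"].sum()),
        "mean": float(vals.mean()) if len(vals) else np.nan,
        "q1": q1,
        "median": med,
        "q3": q3,
        "iqr": (q3 - q1) if len(vals) else np.nan,
    }


def read_counts(path) -> pd.DataFrame:
    """Read a tab-separated poolcount-style table and validate it."""
    counts = pd.read_csv(path, sep="\t")
    _validate(counts)
    return counts
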
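"""Taxonomic diversity estimators for OTU count profiles.

Companions to the sequence-diversity index Nd: the Shannon index H'
(maximum-likelihood and Bayesian-pseudocount variants, natural-log
units) and the Turing-Good coverage of an OTU profile (one minus the
singleton fraction), used to judge whether an OTU table is sampled
deeply enough for H' to be trustworthy.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


def _as_counts(counts: Sequence[float]) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if arr.size == 0:
        raise ValueError("empty OTU list")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    return arr


def shannon_mle(counts: Sequence[float]) -> float:
    """Maximum-likelihood (plug-in) Shannon index, in nats.

    H' = −Σ p_i ln p_i with p_i the observed frequencies; zero-count OTUs
    contribute nothing.
    """
    arr = _as_counts(counts)
    total = arr.sum()
    if total == 0:
        raise ValueError("all counts are zero")
    p = arr[arr > 0] / total
    return float(-np.sum(p * np.log(p)))


def shannon_bayes(counts: Sequence[float], prior: float = 1.0) -> float:
    """Shannon index of Dirichlet posterior-mean frequencies, in nats.

    With a symmetric Dirichlet prior (Laplace prior: ``prior=1``) over all
    S listed OTUs — explicit zeros included — the posterior-mean frequency
    of OTU i is (count_i + prior)/(n + S·prior), and H' is the plug-in
    entropy of those frequencies.
    """
    if prior <= 0:
        raise ValueError("prior must be positive")
    arr = _as_counts(counts)
    p = (arr + prior) / (arr.sum() + arr.size * prior)
    return float(-np.sum(p * np.log(p)))


def turing_good_coverage(counts: Sequence[float]) -> float:
    """Turing-Good sample coverage of an OTU profile: 1 − F₁/n, with F₁
    the number of singleton OTUs and n the total count."""
    arr = _as_counts(counts)
    total = arr.sum()
    if total == 0:
        raise ValueError("all counts are zero")
    singletons = float(np.count_nonzero(arr == 1))
    return 1.0 - singletons / float(total)


def read_otu_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV OTU table (OTU id column + per-sample count columns).

    ``#``-prefixed comment lines are skipped. A single-column file is
    treated as one unnamed sample of counts (no id column).
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    # header row present if first row is non-numeric beyond the id column
    first = df.iloc[0]
    if df.shape[1] > 1 and any(
        not _is_number(v) for v in first.iloc[1:]
    ):
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df.set_index(df.columns[0])
    elif df.shape[1] > 1:
        df = df.set_index(0)
        df.columns = [f"sample_{i}" for i in range(df.shape[1])]
    else:
        if not _is_number(first.iloc[0]):
            df = df.iloc[1:]
        df.columns = ["sample_0"]
    out = df.astype(float)
    if (out < 0).any().any():
        raise ValueError("OTU table contains negative counts")
    return out


def _is_number(value) -> bool:
    try:
        float(value)
        return True
    except (TypeError, ValueError):
        return False


def diversity_summary(table: pd.DataFrame, prior: float = 1.0) -> pd.DataFrame:
    """Per-sample H' (MLE and Bayes) and Turing-Good coverage."""
    rows = {}
    for sample in table.columns:
        counts = table[sample].to_numpy()
        rows[sample] = {
            "shannon_mle": shannon_mle(counts) if counts.sum() > 0 else np.nan,
            "shannon_bayes": shannon_bayes(counts, prior=prior),
            "turing_good_coverage": (
                turing_good_coverage(counts) if counts.sum() > 0 else np.nan
            ),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
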
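"""Summaries and cross-analyses of per-gene selection statistics."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_HIST_EDGES = tuple([i / 10 for i in range(11)] + [1.5, 2.0, math.inf])

# Kyte & Doolittle residue hydropathy values
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    stderr_slope: float
    n_dropped: int = 0


def regress(y: Sequence[float], x: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x; non-finite pairs dropped and counted."""
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if len(xa) != len(ya):
        raise ValueError("x and y must be the same length")
    ok = np.isfinite(xa) & np.isfinite(ya)
    n_dropped = int((~ok).sum())
    xa, ya = xa[ok], ya[ok]
    if len(xa) < 2:
        raise ValueError("need at least 2 finite points for a regression")
    if np.ptp(xa) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(xa, ya)
    r2 = 0.0 if math.isnan(res.rvalue) else float(res.rvalue) ** 2
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_points=len(xa),
        stderr_slope=float(res.stderr),
        n_dropped=n_dropped,
    )


def summarize_genes(
    table: pd.DataFrame,
    hist_edges: Sequence[float] = DEFAULT_HIST_EDGES,
    high_coverage_threshold: float = 20.0,
) -> dict:
    """Distribution summaries of a per-gene table with ``dnds`` and ``category``.

    Means are over finite ratios only; NaN and Inf genes are counted
    separately. Category rows appear only for categories present.
    """
    if table.empty:
        raise ValueError("empty gene table")
    dnds = table["dnds"].to_numpy(dtype=np.float64)
    finite = np.isfinite(dnds)
    out: dict = {
        "n_genes": int(len(table)),
        "n_finite": int(finite.sum()),
        "n_nan": int(np.isnan(dnds).sum()),
        "n_inf": int(np.isinf(dnds).sum()),
        "mean_dnds": float(dnds[finite].mean()) if finite.any() else math.nan,
        "fraction_below_1": (
            float((dnds[finite] < 1).mean()) if finite.any() else math.nan
        ),
    }
    edges = np.asarray(hist_edges, dtype=np.float64)
    counts, _ = np.histogram(dnds[finite], bins=edges)
    out["histogram"] = {
        f"[{edges[i]:g},{edges[i+1]:g})": int(c) for i, c in enumerate(counts)
    }
    by_cat = {}
    if "category" in table.columns:
        for cat, sub in table.groupby("category"):
            v = sub["dnds"].to_numpy(dtype=np.float64)
            f = np.isfinite(v)
            if not len(v):
                continue
            by_cat[cat] = {
                "n_genes": int(len(v)),
                "mean_dnds": float(v[f].mean()) if f.any() else math.nan,
                "fraction_below_1": float((v[f] < 1).mean()) if f.any() else math.nan,
            }
    out["by_category"] = by_cat
    if "avg_read_depth" in table.columns:
        high = table[table["avg_read_depth"] > high_coverage_threshold]
        out["n_high_coverage"] = int(len(high))
    return out


def compare_homolog_populations(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    homolog_pairs: Mapping[str, str] | Sequence[tuple[str, str]],
) -> tuple[pd.DataFrame, RegressionResult, dict]:
    """Square-root-transformed comparison of per-gene dN/dS between two
    populations over homologous gene pairs.

    ``stats_a``/``stats_b`` index loci and carry a ``dnds`` column.
    Pairs where either side is NaN (no polymorphisms) or Inf (no
    synonymous polymorphisms) are dropped from the regression and
    counted; genes with dN/dS > 1 in exactly one population are listed
    as discordant.
    """
    pairs = list(homolog_pairs.items()) if isinstance(homolog_pairs, Mapping) else list(homolog_pairs)
    a_idx = stats_a.set_index("locus") if "locus" in stats_a.columns else stats_a
    b_idx = stats_b.set_index("locus") if "locus" in stats_b.columns else stats_b
    rows = []
    for la, lb in pairs:
        if la not in a_idx.index or lb not in b_idx.index:
            continue
        va = float(a_idx.loc[la, "dnds"])
        vb = float(b_idx.loc[lb, "dnds"])
        rows.append((la, lb, va, vb))
    if not rows:
        raise ValueError("no overlapping homolog pairs between the two tables")
    df = pd.DataFrame(rows, columns=["locus_a", "locus_b", "dnds_a", "dnds_b"])
    finite = np.isfinite(df["dnds_a"]) & np.isfinite(df["dnds_b"])
    n_nan = int((df[["dnds_a", "dnds_b"]].isna().any(axis=1)).sum())
    n_inf = int((np.isinf(df[["dnds_a", "dnds_b"]].to_numpy()).any(axis=1)).sum())
    kept = df[finite].copy()
    kept["sqrt_a"] = np.sqrt(kept["dnds_a"])
    kept["sqrt_b"] = np.sqrt(kept["dnds_b"])
    reg = regress(kept["sqrt_b"].to_list(), kept["sqrt_a"].to_list())
    gt1_a = (df["dnds_a"] > 1) | np.isinf(df["dnds_a"])
    gt1_b = (df["dnds_b"] > 1) | np.isinf(df["dnds_b"])
    discordant = df[gt1_a ^ gt1_b]
    counts = {
        "n_pairs": int(len(df)),
        "n_regressed": int(len(kept)),
        "n_dropped_nan": n_nan,
        "n_dropped_inf": n_inf,
        "n_discordant": int(len(discordant)),
        "discordant_loci": list(
            zip(discordant["locus_a"].to_list(), discordant["locus_b"].to_list())
        ),
    }
    return kept, reg, counts


def hydropathy_profile(protein: str, window: int = 19) -> np.ndarray:
    """Kyte–Doolittle sliding-window mean hydropathy.

    One value per position with a complete centered window; raises for
    sequences shorter than the window.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    seq = protein.upper().rstrip("*")
    if len(seq) < window:
        raise ValueError(f"sequence length {len(seq)} shorter than window {window}")
    try:
        vals = np.array([KYTE_DOOLITTLE[a] for a in seq])
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from exc
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    return (csum[window:] - csum[:-window]) / window
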
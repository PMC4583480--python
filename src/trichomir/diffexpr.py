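"""Two-library differential expression and flat-term enrichment.

Expression is normalized as transcript-per-million (TPM) over the clean-read
total of each library.  Significance of a count difference between the two
(unreplicated) libraries is an exact Audic–Claverie test: conditional on the
count ``x`` observed in one library, the count in the other follows a
negative-binomial predictive distribution with library-size odds
``p = N1/(N1+N2)``.  The raw conditional is asymmetric in the two libraries
by one count, so the two-sided p-value implemented here averages each
directional tail over both conditioning orientations and doubles the smaller
direction (capped at 1) — exactly exchange-symmetric:
``p(x, N1, y, N2) == p(y, N2, x, N1)``.

A miRNA is called differentially expressed when p < 0.05, the
Benjamini–Hochberg q-value < 0.05 and |log2 ratio| > 1 (trichomes over
leaves, zero TPM floored).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class DEConfig:
    p_threshold: float = 0.05
    q_threshold: float = 0.05
    log2_threshold: float = 1.0
    tpm_floor: float = 0.01  # stands in for zero TPM in fold changes
    test: str = "audic-claverie"  # or "fisher"


def tpm(count: int | float, library_total: int) -> float:
    """Transcript-per-million: count / clean-read total x 1e6."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    if count < 0:
        raise ValueError("count must be nonnegative")
    return count / library_total * 1e6


def audic_claverie_test(x: int, n1: int, y: int, n2: int) -> float:
    """Symmetrized two-sided Audic–Claverie exact p-value.

    ``x``/``y`` are the counts in libraries of ``n1``/``n2`` total reads.
    """
    for v, name in ((x, "x"), (y, "y")):
        if v < 0:
            raise ValueError(f"count {name} must be nonnegative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    p1 = n1 / (n1 + n2)
    p2 = n2 / (n1 + n2)
    # conditional on x: Y ~ NB(r=x+1, p=p1); conditional on y: X ~ NB(r=y+1, p=p2)
    up_1 = stats.nbinom.sf(y - 1, x + 1, p1)  # P(Y >= y | x)
    up_2 = stats.nbinom.cdf(x, y + 1, p2)  # P(X <= x | y)
    down_1 = stats.nbinom.cdf(y, x + 1, p1)  # P(Y <= y | x)
    down_2 = stats.nbinom.sf(x - 1, y + 1, p2)  # P(X >= x | y)
    direction_up = 0.5 * (up_1 + up_2)
    direction_down = 0.5 * (down_1 + down_2)
    return float(min(1.0, 2.0 * min(direction_up, direction_down)))


def fisher_test(x: int, n1: int, y: int, n2: int) -> float:
    """Two-sided Fisher's exact test on the 2x2 count table."""
    _, p = stats.fisher_exact([[x, n1 - x], [y, n2 - y]])
    return float(p)


def two_library_test(x: int, n1: int, y: int, n2: int, method: str = "audic-claverie") -> float:
    if method == "audic-claverie":
        return audic_claverie_test(x, n1, y, n2)
    if method == "fisher":
        return fisher_test(x, n1, y, n2)
    raise ValueError(f"unknown test {method!r}")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def log2_ratio(tpm_num: float, tpm_den: float, floor: float = 0.01) -> float:
    """log2 fold change with a floor replacing zero TPM."""
    return float(np.log2(max(tpm_num, floor) / max(tpm_den, floor)))


def call_de(
    counts: Mapping[str, tuple[int, int]],
    totals: tuple[int, int],
    cfg: DEConfig = DEConfig(),
) -> pd.DataFrame:
    """Differential-expression calls for id -> (count_leaves, count_trichomes).

    ``totals`` are the clean-read totals (leaves, trichomes).  The returned
    frame has one row per id with TPMs, log2 ratio (trichomes/leaves),
    p-value, BH q-value and the call in {up, down, ns}.
    """
    n1, n2 = totals
    ids = sorted(counts)
    rows = []
    for mid in ids:
        x, y = counts[mid]
        t1, t2 = tpm(x, n1), tpm(y, n2)
        rows.append(
            {
                "id": mid,
                "count_leaves": x,
                "count_trichomes": y,
                "tpm_leaves": t1,
                "tpm_trichomes": t2,
                "log2_ratio": log2_ratio(t2, t1, cfg.tpm_floor),
                "p_value": two_library_test(x, n1, y, n2, cfg.test),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(q_value=[], call=[])
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    significant = (df["p_value"] < cfg.p_threshold) & (df["q_value"] < cfg.q_threshold)
    call = np.where(
        significant & (df["log2_ratio"] > cfg.log2_threshold),
        "up",
        np.where(significant & (df["log2_ratio"] < -cfg.log2_threshold), "down", "ns"),
    )
    df["call"] = call
    return df


def enrich_terms(
    selected: Iterable[str],
    annotation: Mapping[str, set[str] | frozenset[str]],
    universe: Iterable[str],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of flat terms with BH correction.

    ``annotation`` maps each universe member to its term set.  A term is
    enriched when its corrected p-value is at or below ``q_threshold``.
    """
    universe = sorted(set(universe))
    selected = sorted(set(selected))
    if not selected:
        raise ValueError("empty selection")
    missing = set(selected) - set(universe)
    if missing:
        raise ValueError(f"selected ids missing from universe: {sorted(missing)[:5]}")
    n_universe = len(universe)
    n_selected = len(selected)
    term_pop: dict[str, int] = {}
    term_hit: dict[str, int] = {}
    sel = set(selected)
    for member in universe:
        for term in annotation.get(member, ()):
            term_pop[term] = term_pop.get(term, 0) + 1
            if member in sel:
                term_hit[term] = term_hit.get(term, 0) + 1
    rows = []
    for term in sorted(term_pop):
        k = term_hit.get(term, 0)
        big_k = term_pop[term]
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_selected))
        rows.append(
            {
                "term": term,
                "sample_hit": k,
                "sample_size": n_selected,
                "population_hit": big_k,
                "population_size": n_universe,
                "p_value": min(1.0, p),
            }
        )
    df = pd.DataFrame(rows)
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    df["enriched"] = df["q_value"] <= q_threshold
    return df
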
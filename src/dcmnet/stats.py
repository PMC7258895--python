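"""Group statistics: laterality relabelling, normality screening, Monte-Carlo
permutation tests and false-discovery-rate adjustment.

The comparison of interest is paretic vs non-paretic passive movement, tested
per coupling (and optionally per input gain and hemodynamic parameter) with a
two-sided unpaired permutation test on the difference of condition means.
When the total number of group relabellings is small enough the test
enumerates them exhaustively (exact mode); otherwise it draws random
relabellings and uses the add-one estimator ``p = (1 + b) / (n_perm + 1)``,
which can never return zero. Raw p-values are adjusted within each parameter
pool by Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "relabel_laterality",
    "shapiro_wilk",
    "permutation_test",
    "bh_fdr",
    "compare_conditions",
    "StatTable",
]

#: Anatomical hemisphere prefixes accepted by the relabeller.
_SIDE_PREFIX = {"L": "left", "R": "right"}


def relabel_laterality(label: str, moved_side: str) -> str:
    """Map an anatomical label like ``L_M1`` to laterality form (``cM1``/``iM1``).

    Regions in the hemisphere *opposite* the moved ankle are contralateral
    (prefix ``c``), same-side regions ipsilateral (``i``). Relabelling twice
    with flipped sides returns the original laterality class.
    """
    if moved_side not in ("left", "right"):
        raise ValueError("moved_side must be 'left' or 'right'")
    try:
        side, region = label.split("_", 1)
        hemisphere = _SIDE_PREFIX[side]
    except (ValueError, KeyError):
        raise ValueError(f"unrecognized anatomical label {label!r}; expected e.g. 'L_M1'")
    return ("c" if hemisphere != moved_side else "i") + region


def shapiro_wilk(values) -> Tuple[float, float]:
    """Shapiro-Wilk W statistic and approximate p-value (Royston algorithm)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    res = scipy.stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def permutation_test(
    x,
    y,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> float:
    """Two-sided unpaired permutation p-value for the difference of means.

    Exact when ``C(n_x + n_y, n_x) <= n_perm`` (full enumeration, identity
    split included); Monte-Carlo with the add-one estimator otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need at least 2 observations")
    if n_perm < 1000:
        raise ValueError("n_perm must be at least 1000")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("degenerate pooled sample (all values identical); p = 1", stacklevel=2)
        return 1.0
    nx, n_tot = len(x), len(pooled)
    d_obs = abs(x.mean() - y.mean())
    total = pooled.sum()
    # mean difference as a function of the x-group sum only
    scale = 1.0 / nx + 1.0 / (n_tot - nx)

    n_exact = math.comb(n_tot, nx)
    eps = 1e-12 * max(1.0, float(np.max(np.abs(pooled))))
    if n_exact <= n_perm:
        count = 0
        for idx in combinations(range(n_tot), nx):
            sx = pooled[list(idx)].sum()
            d = abs(sx * scale - total / (n_tot - nx))
            if d >= d_obs - eps:
                count += 1
        return count / n_exact

    rng = np.random.default_rng(seed)
    b = 0
    chunk = 20_000
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        order = np.argsort(rng.random((m, n_tot)), axis=1)[:, :nx]
        sx = pooled[order].sum(axis=1)
        d = np.abs(sx * scale - total / (n_tot - nx))
        b += int(np.sum(d >= d_obs - eps))
        done += m
    return (1 + b) / (n_perm + 1)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@dataclass
class StatTable:
    """Per-parameter group summary: condition moments and permutation p-values."""

    table: pd.DataFrame
    n_permutations: int
    seed: Optional[int]

    def significant(self, level: float = 0.05, adjusted: bool = False) -> list:
        col = "p_fdr" if adjusted else "p"
        return list(self.table.loc[self.table[col] <= level, "label"])


def compare_conditions(
    samples: pd.DataFrame,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    conditions: Tuple[str, str] = ("nonparetic", "paretic"),
    pools: Optional[Dict[str, Sequence[str]]] = None,
) -> StatTable:
    """Permutation tests per parameter label with pool-wise FDR adjustment.

    *samples* is a long-format frame with columns ``label, condition,
    subject, value``. All labels form one FDR pool unless *pools* maps pool
    names to label subsets (couplings, input gains and hemodynamic parameters
    are adjusted separately in the full pipeline). Output rows keep sorted
    label order within each pool.
    """
    required = {"label", "condition", "subject", "value"}
    if not required.issubset(samples.columns):
        raise ValueError(f"samples must have columns {sorted(required)}")
    labels = sorted(samples["label"].unique())
    if pools is None:
        pools = {"all": labels}

    ss = np.random.SeedSequence(seed if seed is not None else 0)
    label_seeds = {
        lbl: int(child.generate_state(1)[0] % 2**31)
        for lbl, child in zip(labels, ss.spawn(len(labels)))
    }

    rows = []
    for pool_name, pool_labels in pools.items():
        pvals = []
        pool_rows = []
        for label in sorted(pool_labels):
            sub = samples[samples["label"] == label]
            groups = []
            for cond in conditions:
                vals = sub.loc[sub.condition == cond, "value"].to_numpy(dtype=float)
                if len(vals) == 0:
                    raise ValueError(f"condition {cond!r} missing for label {label!r}")
                groups.append(vals)
            a, b = groups
            p = permutation_test(a, b, n_perm=n_perm, seed=label_seeds[label])
            pvals.append(p)
            pool_rows.append(
                {
                    "label": label,
                    "pool": pool_name,
                    f"mean_{conditions[0]}": a.mean(),
                    f"sd_{conditions[0]}": a.std(ddof=1),
                    f"mean_{conditions[1]}": b.mean(),
                    f"sd_{conditions[1]}": b.std(ddof=1),
                    "p": p,
                }
            )
        adj = bh_fdr(np.asarray(pvals))
        for row, q in zip(pool_rows, adj):
            row["p_fdr"] = float(q)
        rows.extend(pool_rows)

    return StatTable(table=pd.DataFrame(rows), n_permutations=n_perm, seed=seed)
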
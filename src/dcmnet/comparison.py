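"""Family-level random-effects Bayesian model selection.

Per-subject model evidences (session log evidences summed over a subject's
runs) are pooled into family evidences under a uniform within-family prior —
the family evidence is the log-mean of its members' evidences, so unequal
family sizes do not bias the comparison. A variational Dirichlet scheme then
estimates the random-effects posterior over families: the concentration
vector ``alpha`` yields each family's *expected probability*
``alpha_k / sum(alpha)`` (the posterior mean probability that the family
generated a random subject's data) and, by Monte-Carlo sampling from the
Dirichlet, its *exceedance probability* (the posterior probability that the
family is more likely than every other family in the set).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import digamma, logsumexp

from .model_space import FamilyDefinition

__all__ = [
    "EvidenceMatrix",
    "BMSResult",
    "pool_subject_evidence",
    "pool_family_evidence",
    "rfx_bms",
    "exceedance",
    "select_winning_model",
]


@dataclass(frozen=True)
class EvidenceMatrix:
    """Subjects x columns log-evidence values (nats)."""

    values: np.ndarray
    subjects: Tuple[str, ...]
    columns: Tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.subjects), len(self.columns)):
            raise ValueError("evidence matrix shape does not match labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("evidence values must be finite")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "subjects", tuple(self.subjects))
        object.__setattr__(self, "columns", tuple(self.columns))


@dataclass(frozen=True)
class BMSResult:
    """Dirichlet posterior over families with expected/exceedance probabilities."""

    alpha: np.ndarray
    expected_p: np.ndarray
    exceedance_p: Optional[np.ndarray]
    columns: Tuple[str, ...]
    n_mc_samples: int = 0
    seed: Optional[int] = None

    @property
    def winner(self) -> str:
        ep = self.expected_p
        best = np.flatnonzero(ep == ep.max())
        if len(best) > 1:
            raise ValueError(
                "expected probabilities tie between "
                + ", ".join(self.columns[i] for i in best)
                + "; an explicit tie-break is required"
            )
        return self.columns[int(best[0])]


def pool_subject_evidence(session_evidences: Sequence[EvidenceMatrix]) -> EvidenceMatrix:
    """Sum per-model log evidences over a subject's sessions.

    Sessions are treated as conditionally independent data from the same
    subject, so their log evidences add. Every session matrix must cover the
    same subjects and model columns; a subject missing from any session is
    rejected by name.
    """
    if not session_evidences:
        raise ValueError("no evidence matrices given")
    ref = session_evidences[0]
    for ev in session_evidences[1:]:
        if ev.columns != ref.columns:
            raise ValueError("model columns differ between sessions")
        missing = set(ref.subjects) ^ set(ev.subjects)
        if missing:
            raise ValueError(f"subject(s) missing from a session: {sorted(missing)}")
    order = {s: i for i, s in enumerate(ref.subjects)}
    total = np.zeros_like(ref.values)
    for ev in session_evidences:
        rows = [order[s] for s in ev.subjects]
        total[rows] += ev.values
    return EvidenceMatrix(values=total, subjects=ref.subjects, columns=ref.columns)


def pool_family_evidence(
    session_evidences: Sequence[EvidenceMatrix] | EvidenceMatrix,
    families: Sequence[FamilyDefinition],
) -> EvidenceMatrix:
    """Per-subject family log evidences under a uniform within-family prior.

    Family evidence is ``logsumexp(member evidences) - log(family size)``,
    i.e. the log of the mean member likelihood, computed after summing each
    subject's sessions.
    """
    if isinstance(session_evidences, EvidenceMatrix):
        pooled = session_evidences
    else:
        pooled = pool_subject_evidence(session_evidences)
    col_of = {c: i for i, c in enumerate(pooled.columns)}
    fam_vals = np.empty((len(pooled.subjects), len(families)))
    for k, fam in enumerate(families):
        idx = []
        for mid in sorted(fam.member_model_ids):
            key = str(mid)
            if key not in col_of:
                raise ValueError(f"family {fam.name} member {mid} absent from evidence matrix")
            idx.append(col_of[key])
        fam_vals[:, k] = logsumexp(pooled.values[:, idx], axis=1) - np.log(len(idx))
    return EvidenceMatrix(
        values=fam_vals,
        subjects=pooled.subjects,
        columns=tuple(f.name for f in families),
    )


def rfx_bms(
    ev: EvidenceMatrix,
    alpha0: float = 1.0,
    max_iter: int = 10_000,
    tol: float = 1e-4,
) -> BMSResult:
    """Random-effects model selection via the variational Dirichlet scheme.

    Iterates subject responsibilities
    ``u_nk ∝ exp(ev_nk + digamma(alpha_k) - digamma(sum alpha))`` and
    concentration updates ``alpha_k = alpha0 + sum_n u_nk`` until the largest
    change in alpha falls below *tol*. Exceedance probabilities are not
    computed here; see :func:`exceedance`.
    """
    lev = ev.values
    n, K = lev.shape
    alpha = np.full(K, float(alpha0))
    for _ in range(max_iter):
        w = lev + digamma(alpha) - digamma(alpha.sum())
        w = w - w.max(axis=1, keepdims=True)
        u = np.exp(w)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return BMSResult(
        alpha=alpha,
        expected_p=alpha / alpha.sum(),
        exceedance_p=None,
        columns=ev.columns,
    )


def exceedance(
    alpha: np.ndarray,
    n_samples: int = 1_000_000,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Monte-Carlo exceedance probabilities of a Dirichlet posterior.

    Samples ``n_samples`` probability vectors and returns each component's
    argmax frequency; columns therefore sum to 1 up to Monte-Carlo error.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet concentrations must be positive")
    if n_samples < 10**5:
        raise ValueError("use at least 1e5 samples for a stable estimate")
    rng = np.random.default_rng(seed)
    K = len(alpha)
    counts = np.zeros(K, dtype=np.int64)
    chunk = 200_000
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        g = rng.standard_gamma(alpha, size=(m, K))
        counts += np.bincount(np.argmax(g, axis=1), minlength=K)
        done += m
    return counts / n_samples


def attach_exceedance(result: BMSResult, n_samples: int = 1_000_000, seed=None) -> BMSResult:
    """Return a copy of *result* with Monte-Carlo exceedance probabilities."""
    xp = exceedance(result.alpha, n_samples=n_samples, seed=seed)
    return BMSResult(
        alpha=result.alpha,
        expected_p=result.expected_p,
        exceedance_p=xp,
        columns=result.columns,
        n_mc_samples=n_samples,
        seed=seed,
    )


def select_winning_model(s1_result: BMSResult, stim_result: BMSResult) -> int:
    """Model id at the intersection of the two winning families.

    Family names follow ``F_S1_k`` / ``F_stim_k``; the winner of each set
    fixes one factor, and ``id = 3*(s1-1) + stim`` names the mutual model.
    Ties in expected probability are rejected.
    """
    s1_k = int(s1_result.winner.rsplit("_", 1)[1])
    stim_k = int(stim_result.winner.rsplit("_", 1)[1])
    return 3 * (s1_k - 1) + stim_k
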
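"""Synthetic cohorts with the statistical structure the analysis assumes.

Two generator modes cover the two levels at which the downstream stages
consume data:

* ``parameter_table`` — subject-level connection-strength estimates drawn per
  condition from Gaussians whose means/SDs default to the published group
  summaries of the winning model's 28 couplings (``DEFAULT_CONNECTION_MOMENTS``).
  With ``moment_match=True`` each drawn sample is affinely standardized so its
  sample mean and sample SD (ddof=1) equal the configured values exactly.
* ``bold_sessions`` — full BOLD sessions: per-subject coupling matrices built
  from the parameter draws, input gains and jittered hemodynamic parameters,
  pushed through :func:`dcmnet.forward.integrate_dcm`.

The emulated design is 10 subjects x 2 conditions (non-paretic / paretic
passive ankle movement), 100 volumes at TR = 4 s, alternating 40 s blocks
starting with rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .forward import (
    DCMParameters,
    HemodynamicParams,
    NoiseSpec,
    SessionData,
    StimulusDesign,
    integrate_dcm,
    is_stable,
)
from .model_space import ModelSpec, REGIONS, get_model

__all__ = [
    "CONDITIONS",
    "DEFAULT_CONNECTION_MOMENTS",
    "ConnectionMoments",
    "CohortConfig",
    "make_design",
    "generate_parameter_cohort",
    "generate_bold_cohort",
]

CONDITIONS: Tuple[str, str] = ("nonparetic", "paretic")

#: Published group summaries of the winning model's couplings, used as the
#: generator's target moments: label -> (mean, SD) per condition, Hz.
#: Labels are ``source->target``; self-couplings are the effective (negative)
#: diagonal values.
DEFAULT_CONNECTION_MOMENTS: Dict[str, Dict[str, Tuple[float, float]]] = {
    "cM1->cM1": {"nonparetic": (-0.0925, 0.0227), "paretic": (-0.1389, 0.0489)},
    "cM1->cPM": {"nonparetic": (0.0224, 0.1058), "paretic": (0.1086, 0.0742)},
    "cM1->cSMA": {"nonparetic": (0.0903, 0.1060), "paretic": (0.0636, 0.1118)},
    "cM1->iM1": {"nonparetic": (0.1649, 0.0438), "paretic": (0.2651, 0.1101)},
    "cPM->cM1": {"nonparetic": (0.0174, 0.0667), "paretic": (0.0648, 0.0597)},
    "cPM->cPM": {"nonparetic": (-0.1339, 0.0295), "paretic": (-0.1051, 0.0388)},
    "cPM->cSMA": {"nonparetic": (0.1345, 0.0896), "paretic": (0.0592, 0.0671)},
    "cS1->cM1": {"nonparetic": (0.03680, 0.0361), "paretic": (0.0361, 0.0514)},
    "cS1->cPM": {"nonparetic": (-0.0168, 0.0401), "paretic": (-0.0064, 0.0694)},
    "cS1->cS1": {"nonparetic": (-0.1021, 0.0281), "paretic": (-0.1688, 0.0579)},
    "cSMA->cM1": {"nonparetic": (0.0886, 0.0511), "paretic": (6.3100e-06, 0.0871)},
    "cSMA->cPM": {"nonparetic": (0.244, 0.1376), "paretic": (0.1206, 0.1464)},
    "cSMA->cSMA": {"nonparetic": (-0.1780, 0.0340), "paretic": (-0.1350, 0.0336)},
    "cSMA->iSMA": {"nonparetic": (0.2755, 0.0797), "paretic": (0.3023, 0.0896)},
    "iM1->cM1": {"nonparetic": (0.1752, 0.0834), "paretic": (0.2795, 0.1319)},
    "iM1->iM1": {"nonparetic": (-0.1062, 0.0287), "paretic": (-0.1303, 0.0413)},
    "iM1->iPM": {"nonparetic": (-0.0003, 0.1588), "paretic": (0.0155, 0.1001)},
    "iM1->iSMA": {"nonparetic": (0.0727, 0.0605), "paretic": (0.0932, 0.0924)},
    "iPM->iM1": {"nonparetic": (-0.0024, 0.1094), "paretic": (-0.0237, 0.0260)},
    "iPM->iPM": {"nonparetic": (-0.1310, 0.0517), "paretic": (-0.1332, 0.0544)},
    "iPM->iSMA": {"nonparetic": (0.0304, 0.0757), "paretic": (0.1112, 0.1245)},
    "iS1->iM1": {"nonparetic": (0.0382, 0.0849), "paretic": (0.0363, 0.0716)},
    "iS1->iPM": {"nonparetic": (-0.0414, 0.1473), "paretic": (-0.0286, 0.0712)},
    "iS1->iS1": {"nonparetic": (-0.1870, 0.0784), "paretic": (-0.1391, 0.0473)},
    "iSMA->cSMA": {"nonparetic": (0.3144, 0.1231), "paretic": (0.2658, 0.0669)},
    "iSMA->iM1": {"nonparetic": (0.1054, 0.0548), "paretic": (0.0262, 0.0893)},
    "iSMA->iPM": {"nonparetic": (0.1260, 0.0971), "paretic": (0.1808, 0.1623)},
    "iSMA->iSMA": {"nonparetic": (-0.1316, 0.0337), "paretic": (-0.1709, 0.0393)},
}


@dataclass(frozen=True)
class ConnectionMoments:
    """Target per-condition means/SDs for every coupling of one model."""

    moments: Dict[str, Dict[str, Tuple[float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_CONNECTION_MOMENTS)
    )

    def __post_init__(self) -> None:
        for label, per_cond in self.moments.items():
            for cond, (_, sd) in per_cond.items():
                if sd <= 0:
                    raise ValueError(f"SD must be positive ({label}, {cond})")

    @property
    def labels(self) -> List[str]:
        return list(self.moments)

    def validate_against(self, spec: ModelSpec) -> None:
        expected = set(spec.connection_labels())
        if set(self.moments) != expected:
            missing = expected - set(self.moments)
            extra = set(self.moments) - expected
            raise ValueError(
                f"moments do not cover the model's couplings (missing {sorted(missing)}, "
                f"extra {sorted(extra)})"
            )


def make_design(TR: float = 4.0, session: float = 400.0, block: float = 40.0) -> StimulusDesign:
    """Block design for a *session*-second run; rest block first."""
    n = session / TR
    if abs(n - round(n)) > 1e-9:
        raise ValueError("session length must be divisible by TR")
    return StimulusDesign(TR=TR, n_volumes=int(round(n)), block_length=block, initial_rest=block)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generator settings emulating the study design."""

    n_subjects: int = 10
    conditions: Tuple[str, str] = CONDITIONS
    design: StimulusDesign = field(default_factory=make_design)
    mode: str = "parameter_table"  # or "bold_sessions"
    moment_match: bool = True
    condition_correlation: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("cohort requires at least 2 subjects")
        if not -1.0 < self.condition_correlation <= 1.0:
            raise ValueError("condition correlation must lie in (-1, 1]")
        if self.mode not in ("parameter_table", "bold_sessions"):
            raise ValueError("mode must be 'parameter_table' or 'bold_sessions'")


def _standardize(z: np.ndarray) -> np.ndarray:
    sd = z.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate draw: zero sample SD")
    return (z - z.mean()) / sd


def generate_parameter_cohort(
    cfg: CohortConfig,
    moments: Optional[ConnectionMoments] = None,
) -> pd.DataFrame:
    """Subject-level coupling estimates per condition, long format.

    Returns a DataFrame with columns ``label, condition, subject, value``.
    With ``cfg.moment_match`` the per-condition sample moments (mean, SD with
    ddof=1) equal the configured targets to machine precision; draws are
    independent across connections and, by default, across conditions
    (``condition_correlation`` induces paired structure when nonzero).
    """
    moments = moments or ConnectionMoments()
    if cfg.moment_match and cfg.n_subjects < 2:
        raise ValueError("moment matching requires at least 2 subjects")
    rng = np.random.default_rng(cfg.seed)
    rho = cfg.condition_correlation
    rows = []
    subjects = [f"S{i + 1:02d}" for i in range(cfg.n_subjects)]
    for label in moments.labels:
        z_a = rng.standard_normal(cfg.n_subjects)
        z_b = rho * z_a + np.sqrt(1.0 - rho**2) * rng.standard_normal(cfg.n_subjects)
        for cond, z in zip(cfg.conditions, (z_a, z_b)):
            mean, sd = moments.moments[label][cond]
            if cfg.moment_match:
                vals = mean + sd * _standardize(z)
            else:
                vals = mean + sd * z
            rows.extend(
                {"label": label, "condition": cond, "subject": s, "value": float(x)}
                for s, x in zip(subjects, vals)
            )
    return pd.DataFrame(rows, columns=["label", "condition", "subject", "value"])


def _params_from_draws(
    spec: ModelSpec,
    values: Dict[str, float],
    hemo: HemodynamicParams,
    c_gain: float,
    stabilize: bool,
    margin: float,
) -> DCMParameters:
    """Assemble DCMParameters from one subject-condition's coupling draws.

    When *stabilize* is set and the sampled coupling matrix has an eigenvalue
    with real part above ``-margin``, a uniform negative shift is applied to
    the diagonal so the system decays; the self log-scales are back-solved
    from the shifted diagonal.
    """
    labels = {r: i for i, r in enumerate(spec.region_labels)}
    n = len(spec.region_labels)
    A = np.zeros((n, n))
    diag = np.zeros(n)
    for label, val in values.items():
        src, tgt = label.split("->")
        i, j = labels[tgt], labels[src]
        if i == j:
            diag[i] = val
        else:
            A[i, j] = val

    a_eff = A.copy()
    np.fill_diagonal(a_eff, diag)
    lam = np.linalg.eigvals(a_eff).real.max()
    shift = 0.0
    if stabilize and (lam > -margin or diag.max() > -margin):
        shift = max(lam + margin, diag.max() + margin)
        diag = diag - shift
    if np.any(diag >= 0):
        raise ValueError("sampled self-couplings must be negative")
    self_log = np.log(-diag / 0.5)
    C = np.where(np.asarray(spec.c_mask), c_gain, 0.0)
    return DCMParameters(A=A, self_log_scale=self_log, C=C, hemo=hemo)


def generate_bold_cohort(
    cfg: CohortConfig,
    moments: Optional[ConnectionMoments] = None,
    spec: Optional[ModelSpec] = None,
    c_gain: float = 0.5,
    hemo_log_sd: float = 0.1,
    noise: Optional[NoiseSpec] = NoiseSpec(),
    stabilize: bool = True,
    stability_margin: float = 0.25,
    max_retries: int = 20,
) -> List[SessionData]:
    """Simulate one BOLD session per subject and condition (2 x n_subjects).

    Per-subject coupling matrices come from :func:`generate_parameter_cohort`;
    input gains sit at *c_gain* on the model's driven regions and per-region
    hemodynamic parameters are log-normally jittered (log-SD *hemo_log_sd*)
    around the priors. Unstable draws are shifted to stability (default) or
    resampled up to *max_retries* when ``stabilize=False``.
    """
    spec = spec or get_model(11)
    moments = moments or ConnectionMoments()
    moments.validate_against(spec)
    n = len(spec.region_labels)

    table = generate_parameter_cohort(cfg, moments)
    ss = np.random.SeedSequence(cfg.seed if cfg.seed is not None else 0)
    hemo_seed, sim_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    hemo_rng = np.random.default_rng(hemo_seed)

    sessions: List[SessionData] = []
    subjects = sorted(table["subject"].unique())
    for si, subj in enumerate(subjects):
        for cond in cfg.conditions:
            sub = table[(table.subject == subj) & (table.condition == cond)]
            values = dict(zip(sub.label, sub.value))
            session_seed = int((sim_seed + 1000 * si + (0 if cond == cfg.conditions[0] else 1)) % 2**31)
            attempt = 0
            while True:
                hemo = HemodynamicParams.from_log_scales(
                    *(hemo_log_sd * hemo_rng.standard_normal(n) for _ in range(3))
                )
                try:
                    params = _params_from_draws(
                        spec, values, hemo, c_gain, stabilize, stability_margin
                    )
                    if not stabilize and not is_stable(params.a_eff):
                        raise FloatingPointError("unstable draw")
                    sessions.append(
                        integrate_dcm(
                            spec,
                            params,
                            cfg.design,
                            noise=noise,
                            seed=session_seed,
                            condition=cond,
                            subject=subj,
                        )
                    )
                    break
                except (ValueError, FloatingPointError):
                    # unstable draw: resample this subject-condition, bounded retries
                    attempt += 1
                    if attempt > max_retries:
                        raise RuntimeError(
                            f"no stable parameter draw for subject {subj} ({cond}) "
                            f"after {max_retries} retries"
                        )
                    redraw = np.random.default_rng(hemo_rng.integers(2**31))
                    values = {
                        k: moments.moments[k][cond][0]
                        + moments.moments[k][cond][1] * redraw.standard_normal()
                        for k in values
                    }
    return sessions
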
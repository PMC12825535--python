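"""Seeded synthetic cohorts with the structure the pipeline stages assume.

The generator emulates a biobank-style prospective design: ~2,900
approximately standard-normal NPX protein variables measured once at
baseline, a rare incident cancer (~0.3% cumulative incidence over ~12 years
of median follow-up), baseline covariates, MCAR missingness, planted
proportional-hazards protein effects, four pre-diagnostic trajectory
archetypes whose shapes enter case NPX as a function of lead time to
diagnosis, and an exposure → mediator-protein → hazard mediation structure
for a continuous (BMI-like) and a binary (smoking-like) exposure.

Everything is driven by a single integer seed; two runs with the same
config are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "MediationSpec",
    "GroundTruth",
    "archetype_shape",
    "simulate_cohort",
    "write_outputs",
    "study_like_config",
]

_ARCHETYPES = (1, 2, 3, 4)
# archetype 1: z(t) = a exp(-b t) with z(15) = 1.0 (early-abnormal, rising
# sharply toward diagnosis); 2: persistently elevated plateau; 3: logistic
# step centred 3 y pre-diagnosis; 4: Gaussian bump peaking 15 y out.
_A1_PEAK = 3.0
_A1_RATE = np.log(3.0) / 15.0
_A2_LEVEL = 0.8
_A3_HEIGHT = 0.9
_A3_CENTER = 3.0
_A3_SCALE = 0.8
_A4_HEIGHT = 0.9
_A4_CENTER = 15.0
_A4_SD = 4.0


def archetype_shape(archetype: int, lead_time):
    """Mean case z-score offset for a trajectory archetype.

    Parameters
    ----------
    archetype : one of 1..4
    lead_time : years between blood draw and diagnosis, in [0, 15]
        (0 = at diagnosis, 15 = fifteen years before it).

    Shapes, in z-units relative to matched controls:

    1. exponential rise peaking at diagnosis, already abnormal (z = 1.0)
       fifteen years out;
    2. persistently elevated, stable (z = 0.8 throughout);
    3. sharp logistic rise to z = 0.9 within ~3 years of diagnosis, then
       plateau;
    4. Gaussian bump peaked fifteen years out (z = 0.9) declining back to
       normal as diagnosis approaches.
    """
    t = np.asarray(lead_time, dtype=float)
    if np.any((t < 0) | (t > 15)):
        raise ValueError("lead_time must lie in [0, 15] years")
    if archetype == 1:
        out = _A1_PEAK * np.exp(-_A1_RATE * t)
    elif archetype == 2:
        out = np.full_like(t, _A2_LEVEL)
    elif archetype == 3:
        out = _A3_HEIGHT / (1.0 + np.exp((t - _A3_CENTER) / _A3_SCALE))
    elif archetype == 4:
        out = _A4_HEIGHT * np.exp(-((t - _A4_CENTER) ** 2) / (2 * _A4_SD**2))
    else:
        raise ValueError(f"unknown archetype id: {archetype!r}")
    return out if out.ndim else float(out)


def _shape_clamped(archetype: int, lead_time):
    """Shape with lead times beyond 15 y clamped to the 15-y value."""
    return archetype_shape(archetype, np.clip(lead_time, 0.0, 15.0))


@dataclass
class MediationSpec:
    """Exposure → mediator-protein → hazard structure planted in the cohort.

    The mediator model is ``M_p = beta1_p * A + mediator_sd * eps`` and the
    log hazard gains ``theta1*A + sum_p (theta2*M_p + theta3*A*M_p)``.
    ``A`` is the standardized BMI (``exposure='bmi'``) or the 0/1
    ever-smoking indicator (``exposure='smoking'``).
    """

    exposure: str = "bmi"  # 'bmi' (continuous standardized) or 'smoking' (binary)
    mediators: dict[str, float] = field(default_factory=dict)  # protein -> beta1
    theta1: float = 0.0
    theta2: float = 0.0
    theta3: float = 0.0
    mediator_sd: float = 1.0

    @property
    def kind(self) -> str:
        return "binary" if self.exposure == "smoking" else "continuous"


@dataclass
class SimConfig:
    n_participants: int = 48_851
    n_proteins: int = 2_911
    event_rate: float = 0.0034
    followup_median: float = 11.76
    missing_rate: float = 0.02
    archetype_assignments: dict[str, int] = field(default_factory=dict)
    signal_log_hr: dict[str, float] = field(default_factory=dict)
    covariate_log_hr: dict[str, float] = field(default_factory=dict)
    mediation_spec: MediationSpec | None = None
    prior_cancer_rate: float = 0.0
    covariate_missing_rate: float = 0.0
    protein_names: list[str] | None = None
    seed: int = 0

    def names(self) -> list[str]:
        if self.protein_names is not None:
            if len(self.protein_names) != self.n_proteins:
                raise ValueError("protein_names length must equal n_proteins")
            return list(self.protein_names)
        width = max(4, len(str(self.n_proteins)))
        return [f"P{i:0{width}d}" for i in range(1, self.n_proteins + 1)]

    def validate(self) -> None:
        if not 0.0 < self.event_rate < 1.0:
            raise ValueError("event_rate must be in (0, 1)")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must be in [0, 0.5]")
        names = set(self.names())
        for label, mapping in [
            ("archetype_assignments", self.archetype_assignments),
            ("signal_log_hr", self.signal_log_hr),
        ]:
            unknown = set(mapping) - names
            if unknown:
                raise ValueError(f"{label} names unknown proteins: {sorted(unknown)}")
        bad = {a for a in self.archetype_assignments.values() if a not in _ARCHETYPES}
        if bad:
            raise ValueError(f"unknown archetype ids: {sorted(bad)}")
        if self.mediation_spec is not None:
            unknown = set(self.mediation_spec.mediators) - names
            if unknown:
                raise ValueError(f"mediators unknown proteins: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Generator-side truth for recovery tests."""

    log_hr: dict[str, float]
    archetypes: dict[str, int]
    cluster_labels: dict[str, int]
    mediation: dict | None
    linear_predictor: np.ndarray
    baseline_hazard: float

    def to_json(self) -> str:
        payload = {
            "log_hr": self.log_hr,
            "archetypes": self.archetypes,
            "cluster_labels": self.cluster_labels,
            "mediation": self.mediation,
            "baseline_hazard": self.baseline_hazard,
            "linear_predictor": np.asarray(self.linear_predictor).tolist(),
        }
        return json.dumps(payload, indent=1)


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [f"ID{i:06d}" for i in range(n)],
            "age": rng.uniform(40.0, 70.0, n),
            "sex": np.where(rng.random(n) < 0.47, "male", "female"),
            "ethnicity": rng.choice(
                ["white", "asian", "black", "other"], size=n, p=[0.94, 0.02, 0.02, 0.02]
            ),
            "deprivation_index": rng.normal(0.0, 3.0, n),
            "smoking": np.where(rng.random(n) < 0.45, "ever", "never"),
            "alcohol": rng.choice(
                ["never", "moderate", "frequent"], size=n, p=[0.2, 0.6, 0.2]
            ),
            "bmi": rng.normal(27.0, 4.5, n),
            "hypertension": (rng.random(n) < 0.30).astype(int),
            "diabetes": (rng.random(n) < 0.06).astype(int),
            "creatinine": rng.normal(72.0, 15.0, n),
        }
    )


def _covariate_numeric(cohort: pd.DataFrame, name: str) -> np.ndarray:
    """Numeric encoding used for planted covariate log-hazard effects."""
    col = cohort[name]
    if name == "sex":
        return (col == "male").to_numpy(float)
    if name == "smoking":
        return (col == "ever").to_numpy(float)
    if name == "alcohol":
        return (col != "never").to_numpy(float)
    if name == "ethnicity":
        return (col != "white").to_numpy(float)
    if name == "age":
        return (col.to_numpy(float) - 55.0) / 10.0
    if name == "bmi":
        return (col.to_numpy(float) - 27.0) / 4.5
    return col.to_numpy(float)


def _calibrate_baseline(eta: np.ndarray, censor: np.ndarray, target: float) -> float:
    """Bisection on log10(lambda0) so E[P(T <= C)] matches ``target``."""
    relhaz = np.exp(eta - eta.max())  # guard overflow; folded back below
    offset = eta.max()

    def incidence(log10_lam: float) -> float:
        lam = 10.0**log10_lam
        return float(np.mean(-np.expm1(-lam * relhaz * censor)))

    lo, hi = -12.0, 4.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if incidence(mid) < target:
            lo = mid
        else:
            hi = mid
    return 10.0 ** (0.5 * (lo + hi)) / np.exp(offset)


def _fourway_truth(spec: MediationSpec) -> dict:
    """Closed-form four-way components at the generator's reference settings.

    Multiple mediators sharing (theta2, theta3) aggregate exactly: the sum of
    independent normal mediators is normal with beta1 = sum(beta1_p) and
    sigma2 = n_mediators * mediator_sd^2.
    """
    from .mediation_fourway import four_way_components

    beta1 = float(sum(spec.mediators.values()))
    sigma2 = len(spec.mediators) * spec.mediator_sd**2
    comps = four_way_components(
        beta0=0.0,
        beta1=beta1,
        sigma2=sigma2,
        theta1=spec.theta1,
        theta2=spec.theta2,
        theta3=spec.theta3,
        a=1.0,
        a_star=0.0,
        m_star=0.0,
        cov_term=0.0,
    )
    return {
        "exposure": spec.exposure,
        "kind": spec.kind,
        "beta1": beta1,
        "theta1": spec.theta1,
        "theta2": spec.theta2,
        "theta3": spec.theta3,
        "sigma2": sigma2,
        "components": comps,
        "proportion_mediated": comps["pie"] / comps["te"] if comps["te"] != 0 else None,
    }


def simulate_cohort(config: SimConfig):
    """Generate ``(CohortTable, ProteinMatrix, GroundTruth)``.

    Event times follow an exponential proportional-hazards model whose
    baseline hazard is calibrated by bisection to the configured cumulative
    incidence under administrative censoring drawn uniformly around the
    configured median follow-up.  Case NPX values additionally carry the
    archetype shape evaluated at the realized lead time; the MCAR mask is
    applied last.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, names = config.n_participants, config.names()
    name_idx = {p: j for j, p in enumerate(names)}

    cohort = _draw_covariates(rng, n)
    Z = rng.standard_normal((n, config.n_proteins))

    med = config.mediation_spec
    if med is not None and med.mediators:
        if med.exposure == "bmi":
            A = (cohort["bmi"].to_numpy() - cohort["bmi"].mean()) / cohort["bmi"].std(ddof=1)
        elif med.exposure == "smoking":
            A = (cohort["smoking"] == "ever").to_numpy(float)
        else:
            raise ValueError(f"unknown mediation exposure: {med.exposure!r}")
        for prot, b1 in med.mediators.items():
            j = name_idx[prot]
            Z[:, j] = b1 * A + med.mediator_sd * Z[:, j]

    eta = np.zeros(n)
    for prot, loghr in config.signal_log_hr.items():
        eta += loghr * Z[:, name_idx[prot]]
    for cov, coef in config.covariate_log_hr.items():
        eta += coef * _covariate_numeric(cohort, cov)
    if med is not None and med.mediators:
        eta += med.theta1 * A
        for prot in med.mediators:
            Mp = Z[:, name_idx[prot]]
            eta += med.theta2 * Mp + med.theta3 * A * Mp

    censor = rng.uniform(config.followup_median - 1.3, config.followup_median + 1.3, n)
    lam0 = _calibrate_baseline(eta, censor, config.event_rate)
    T = rng.standard_exponential(n) / (lam0 * np.exp(eta))
    event = T <= censor
    followup = np.where(event, T, censor)
    lead = np.where(event, T, np.nan)

    cohort["prior_cancer"] = (rng.random(n) < config.prior_cancer_rate).astype(int)
    cohort["followup_time"] = followup
    cohort["event"] = event.astype(int)
    cohort["lead_time"] = lead

    for prot, arch in config.archetype_assignments.items():
        j = name_idx[prot]
        Z[event, j] += _shape_clamped(arch, lead[event])

    if config.missing_rate > 0:
        Z[rng.random(Z.shape) < config.missing_rate] = np.nan
    if config.covariate_missing_rate > 0:
        for cov in ("bmi", "deprivation_index"):
            hole = rng.random(n) < config.covariate_missing_rate
            cohort.loc[hole, cov] = np.nan

    matrix = pd.DataFrame(Z, index=cohort["participant_id"], columns=names)
    cohort = cohort.set_index("participant_id", drop=False)
    cohort.index.name = None

    truth = GroundTruth(
        log_hr={p: float(config.signal_log_hr.get(p, 0.0)) for p in names},
        archetypes={p: int(a) for p, a in config.archetype_assignments.items()},
        cluster_labels={p: int(a) for p, a in config.archetype_assignments.items()},
        mediation=_fourway_truth(med) if med is not None and med.mediators else None,
        linear_predictor=eta,
        baseline_hazard=float(lam0),
    )
    return cohort, matrix, truth


def write_outputs(outdir, cohort: pd.DataFrame, matrix: pd.DataFrame, truth: GroundTruth):
    """Write cohort/protein CSVs (empty cell = missing) and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    matrix.to_csv(outdir / "proteins.csv", index_label="participant_id")
    (outdir / "ground_truth.json").write_text(truth.to_json())
    return outdir


def study_like_config(
    n_participants: int = 5_000,
    n_proteins: int = 300,
    n_hits: int = 24,
    event_rate: float = 0.0034,
    seed: int = 0,
) -> SimConfig:
    """A config with the study's qualitative structure at a chosen scale.

    Plants ``n_hits`` hazard-associated proteins split across the four
    trajectory archetypes (one lone early-exponential protein, then a
    persistent-elevation majority, a late-rise group and an early-peak
    group, mirroring the observed cluster sizes), BMI- and smoking-driven
    mediator proteins, and modest covariate effects.
    """
    width = max(4, len(str(n_proteins)))
    names = [f"P{i:0{width}d}" for i in range(1, n_proteins + 1)]
    hits = names[:n_hits]
    arch = {hits[0]: 1}
    n2 = max(1, (n_hits - 1) * 11 // 23)
    n3 = max(1, (n_hits - 1) * 7 // 23)
    for p in hits[1 : 1 + n2]:
        arch[p] = 2
    for p in hits[1 + n2 : 1 + n2 + n3]:
        arch[p] = 3
    for p in hits[1 + n2 + n3 :]:
        arch[p] = 4
    signal = {hits[0]: np.log(3.0)}
    for p in hits[1:]:
        signal[p] = np.log(1.8)
    return SimConfig(
        n_participants=n_participants,
        n_proteins=n_proteins,
        event_rate=event_rate,
        archetype_assignments=arch,
        signal_log_hr=signal,
        covariate_log_hr={"age": 0.45, "sex": 0.6, "bmi": 0.2, "smoking": 0.35},
        mediation_spec=MediationSpec(
            exposure="bmi",
            mediators={hits[1]: 0.4, hits[2]: 0.3},
            theta1=0.15,
            theta2=0.3,
            theta3=0.0,
        ),
        missing_rate=0.02,
        seed=seed,
    )
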
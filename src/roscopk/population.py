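"""Population layer: covariates, inter-individual variability, residual error.

Individual parameters arise from typical values by covariate adjustment and
log-normal random effects, ``theta_i = theta_cov(z_i) * exp(eta_i)``.
Seven parameters carry inter-individual variability — D50, T1max, dT2max,
CV1, CV2, V and ke, in that fixed order — with two correlated pairs,
(T1max, CV2) and (dT2max, CV1).  pi1, k12, k21 and kmet are population
constants.  Covariates: proton-pump-inhibitor (PPI) co-medication shifts
the absorption timing (multiplicatively, ``exp(beta_ppi)``), and height
scales the apparent volume as a power of height/170 cm.

Residual error is proportional for the parent and combined
(additive + proportional) for the metabolite, on the nmol/L scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .structural import StructuralParams, TYPICAL_PARAMS

#: Order of the random-effect vector eta.
ETA_FIELDS = ("D50", "T1max", "dT2max", "CV1", "CV2", "V", "ke")


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, variability, covariate and error parameters."""

    theta_pop: StructuralParams = TYPICAL_PARAMS
    omega: tuple[float, ...] = (0.689, 0.452, 0.647, 0.426, 0.547, 0.678, 0.393)
    corr_T1max_CV2: float = -0.839
    corr_dT2max_CV1: float = 0.624
    beta_ppi_T1max: float = 0.680
    beta_height_V: float = 6.47
    height_ref: float = 170.0
    err_parent_b: float = 0.297   # proportional SD fraction, parent
    err_met_a: float = 9.20       # additive SD, nmol/L, metabolite
    err_met_b: float = 0.271      # proportional SD fraction, metabolite
    #: which absorption-timing parameter the PPI effect multiplies
    ppi_target: str = "T1max"

    def __post_init__(self) -> None:
        om = tuple(float(w) for w in self.omega)
        if len(om) != len(ETA_FIELDS) or any(w < 0 for w in om):
            raise ValueError(f"omega must be {len(ETA_FIELDS)} non-negative SDs")
        object.__setattr__(self, "omega", om)
        for r in (self.corr_T1max_CV2, self.corr_dT2max_CV1):
            if not -1.0 < r < 1.0:
                raise ValueError(f"correlation must lie in (-1, 1), got {r}")
        for v in (self.err_parent_b, self.err_met_a, self.err_met_b):
            if v < 0:
                raise ValueError("error SDs must be >= 0")
        if self.ppi_target not in ("T1max", "dT2max"):
            raise ValueError(f"ppi_target must be T1max or dT2max, got {self.ppi_target!r}")
        build_eta_covariance(self)  # raises if not positive semi-definite

    def replace(self, **kwargs) -> "PopulationModel":
        return replace(self, **kwargs)

    def omega_of(self, name: str) -> float:
        return self.omega[ETA_FIELDS.index(name)]


@dataclass(frozen=True)
class Subject:
    """One (real or simulated) subject's design and covariates."""

    id: str
    dose_mg: float
    height_cm: float = 170.0
    ppi: bool = False
    eta: np.ndarray | None = None  # optional known random effects, log scale

    def __post_init__(self) -> None:
        if self.height_cm <= 0:
            raise ValueError(f"height_cm must be > 0, got {self.height_cm}")
        if self.dose_mg < 0:
            raise ValueError(f"dose_mg must be >= 0, got {self.dose_mg}")
        if self.eta is not None:
            e = np.asarray(self.eta, dtype=float)
            if e.shape != (len(ETA_FIELDS),):
                raise ValueError(f"eta must have shape ({len(ETA_FIELDS)},)")
            object.__setattr__(self, "eta", e)


def apply_covariates(theta_pop: StructuralParams, subject: Subject,
                     model: PopulationModel) -> StructuralParams:
    """Covariate-adjusted typical parameters for one subject."""
    changes: dict[str, float] = {}
    if subject.ppi:
        tgt = model.ppi_target
        changes[tgt] = getattr(theta_pop, tgt) * float(np.exp(model.beta_ppi_T1max))
    changes["V"] = theta_pop.V * (subject.height_cm / model.height_ref) ** model.beta_height_V
    return theta_pop.replace(**changes)


def build_eta_covariance(model: PopulationModel) -> np.ndarray:
    """7x7 covariance of the random-effect vector (log scale).

    Diagonal ``omega**2``; off-diagonal terms only for the two estimated
    correlation pairs.  Raises ``ValueError`` if the result is not positive
    definite (impossible for |r| < 1 here since the pairs do not overlap,
    unless an omega is zero — zero-variance components are allowed and
    checked as semi-definite).
    """
    om = np.asarray(model.omega, dtype=float)
    cov = np.diag(om**2)
    pairs = ((("T1max", "CV2"), model.corr_T1max_CV2),
             (("dT2max", "CV1"), model.corr_dT2max_CV1))
    for (a, b), r in pairs:
        i, j = ETA_FIELDS.index(a), ETA_FIELDS.index(b)
        cov[i, j] = cov[j, i] = r * om[i] * om[j]
    if np.min(np.linalg.eigvalsh(cov)) < -1e-12:
        raise ValueError("random-effect covariance is not positive semi-definite")
    return cov


#: The final published model (typical values, omegas, correlations, betas).
FINAL_MODEL = PopulationModel()


def sample_eta(model: PopulationModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n random-effect vectors from N(0, Sigma), shape (n, 7)."""
    cov = build_eta_covariance(model)
    # eigendecomposition handles omega = 0 components (singular covariance)
    w, v = np.linalg.eigh(cov)
    root = v * np.sqrt(np.maximum(w, 0.0))
    return rng.standard_normal((n, len(ETA_FIELDS))) @ root.T


def individual_params(model: PopulationModel, subject: Subject,
                      eta: np.ndarray) -> StructuralParams:
    """Combine covariate-adjusted typicals with a given eta vector."""
    base = apply_covariates(model.theta_pop, subject, model)
    changes = {f: getattr(base, f) * float(np.exp(e))
               for f, e in zip(ETA_FIELDS, np.asarray(eta, dtype=float))}
    return base.replace(**changes)


def sample_individual(model: PopulationModel, subject: Subject,
                      rng: np.random.Generator | int) -> StructuralParams:
    """Draw one subject's parameters; uses ``subject.eta`` when present."""
    if subject.eta is not None:
        eta = subject.eta
    else:
        rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
        eta = sample_eta(model, 1, rng)[0]
    return individual_params(model, subject, eta)


def residual_sd(pred, analyte: str, model: PopulationModel):
    """Residual-error SD (nmol/L) at a noise-free prediction.

    Parent: proportional, ``b1 * f``; metabolite: combined,
    ``sqrt(a2^2 + b2^2 f^2)``.
    """
    pred = np.asarray(pred, dtype=float)
    if np.any(pred < 0):
        raise ValueError("predictions must be >= 0")
    if analyte == "parent":
        out = model.err_parent_b * pred
    elif analyte == "metabolite":
        out = np.sqrt(model.err_met_a**2 + model.err_met_b**2 * pred**2)
    else:
        raise ValueError(f"unknown analyte {analyte!r}")
    return float(out) if out.ndim == 0 else out


def add_residual_error(pred, analyte: str, model: PopulationModel,
                       rng: np.random.Generator | int):
    """Observed concentrations y = f + g(f)*eps with eps ~ N(0, 1).

    Values may come out negative at low predictions under the metabolite's
    additive component; censoring at the quantification limit is applied
    downstream, never truncation to zero.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    pred = np.asarray(pred, dtype=float)
    return pred + residual_sd(pred, analyte, model) * rng.standard_normal(pred.shape)


# --- flat serialization with the published parameter names ------------------

_FLAT_KEYS = {
    "D50": ("theta", "D50"), "pi1": ("theta", "pi1"),
    "T1max": ("theta", "T1max"), "dT2max": ("theta", "dT2max"),
    "CV1": ("theta", "CV1"), "CV2": ("theta", "CV2"), "V": ("theta", "V"),
    "k12": ("theta", "k12"), "k21": ("theta", "k21"),
    "kmet": ("theta", "kmet"), "ke": ("theta", "ke"),
}


def model_to_dict(model: PopulationModel) -> dict:
    """Flat key–value form of the model (lossless round trip)."""
    d = {k: getattr(model.theta_pop, f) for k, (_, f) in _FLAT_KEYS.items()}
    d.update({f"omega_{f}": w for f, w in zip(ETA_FIELDS, model.omega)})
    d.update({
        "corr_T1max_CV2": model.corr_T1max_CV2,
        "corr_dT2max_CV1": model.corr_dT2max_CV1,
        "beta_ppi_T1max": model.beta_ppi_T1max,
        "beta_height_V": model.beta_height_V,
        "height_ref": model.height_ref,
        "b1": model.err_parent_b,
        "a2": model.err_met_a,
        "b2": model.err_met_b,
        "ppi_target": model.ppi_target,
    })
    return d


def model_from_dict(d: dict) -> PopulationModel:
    """Inverse of :func:`model_to_dict`; unknown keys are an error."""
    d = dict(d)
    theta = StructuralParams(**{f: float(d.pop(k)) for k, (_, f) in _FLAT_KEYS.items()})
    omega = tuple(float(d.pop(f"omega_{f}")) for f in ETA_FIELDS)
    kwargs = dict(
        theta_pop=theta, omega=omega,
        corr_T1max_CV2=float(d.pop("corr_T1max_CV2")),
        corr_dT2max_CV1=float(d.pop("corr_dT2max_CV1")),
        beta_ppi_T1max=float(d.pop("beta_ppi_T1max")),
        beta_height_V=float(d.pop("beta_height_V")),
        height_ref=float(d.pop("height_ref")),
        err_parent_b=float(d.pop("b1")),
        err_met_a=float(d.pop("a2")),
        err_met_b=float(d.pop("b2")),
        ppi_target=str(d.pop("ppi_target", "T1max")),
    )
    if d:
        raise ValueError(f"unknown model keys: {sorted(d)}")
    return PopulationModel(**kwargs)
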
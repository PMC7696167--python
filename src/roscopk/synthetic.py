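"""Synthetic-trial generator emulating the ROSCO-CF first-dose PK design.

The study design being emulated: 23 adult cystic-fibrosis patients in three
dose arms (9 at 200 mg, 7 at 400 mg, 7 at 800 mg oral roscovitine), blood
sampling pre-dose and at 0.5, 1, 2, 4, 6, 8 and 12 h after the first dose,
both analytes quantified with a 5.00 ng/mL LLOQ, heights spanning
158–182 cm, and 15 of 23 subjects on proton-pump inhibitors.

Generated datasets are long-format tables (one row per subject, time and
analyte) with explicit left-censoring flags; the simulated truth (each
subject's random effects and parameters) is attached so that parameter-
recovery experiments are self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import units
from .fastsolve import pack_params, solve_batch
from .population import (ETA_FIELDS, PopulationModel, Subject,
                         individual_params, sample_eta)
from .units import mg_to_umol

#: Long-format dataset columns, in order.  DVID: 1 = parent, 2 = metabolite.
DATASET_COLUMNS = ("ID", "ARM_MG", "TIME_H", "DVID", "DV_NMOL_L", "CENS",
                   "LLOQ_NMOL_L", "HT_CM", "PPI")

DVID_PARENT = 1
DVID_METABOLITE = 2
_ANALYTE_OF_DVID = {DVID_PARENT: "parent", DVID_METABOLITE: "metabolite"}


@dataclass(frozen=True)
class TrialDesign:
    """Arms, nominal sampling times, quantification limit and covariates."""

    arms: dict[int, int] = field(default_factory=lambda: {200: 9, 400: 7, 800: 7})
    nominal_times: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0)
    lloq_ng_ml: float = 5.00
    height_range: tuple[float, float] = (158.0, 182.0)
    ppi_prevalence: float = 15.0 / 23.0
    missing_rate: float = 0.0   # per post-dose row; 0 keeps the full grid

    def __post_init__(self) -> None:
        if not self.arms or any(n < 1 for n in self.arms.values()):
            raise ValueError("every arm needs at least one subject")
        t = np.asarray(self.nominal_times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("nominal_times must be strictly increasing")
        if self.lloq_ng_ml <= 0:
            raise ValueError("lloq_ng_ml must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_subjects(self) -> int:
        return sum(self.arms.values())


@dataclass
class PKDataset:
    """Observed (or simulated) concentration records plus subject metadata.

    ``obs`` holds one row per (subject, time, analyte) with the columns in
    :data:`DATASET_COLUMNS`; censored rows carry NaN in ``DV_NMOL_L`` and
    the analyte's LLOQ in nmol/L.  ``subjects`` maps each ID to dose and
    covariates.  ``truth`` (optional) carries the simulated random effects
    and individual parameters for recovery experiments.
    """

    obs: pd.DataFrame
    subjects: pd.DataFrame
    truth: pd.DataFrame | None = None

    def subject_list(self) -> list[Subject]:
        return [Subject(id=str(r.ID), dose_mg=float(r.ARM_MG),
                        height_cm=float(r.HT_CM), ppi=bool(r.PPI))
                for r in self.subjects.itertuples()]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def analyte_of_dvid(dvid: int) -> str:
    return _ANALYTE_OF_DVID[int(dvid)]


def generate_trial(model: PopulationModel, design: TrialDesign | None = None,
                   seed: int = 0) -> PKDataset:
    """Simulate one complete trial under the population model.

    Covariates are sampled (height uniform on the design range, PPI
    Bernoulli at the design prevalence), individual parameters follow the
    population model, noise-free profiles are solved at the nominal times,
    residual error is added per analyte and left-censoring applied at the
    analyte-specific LLOQ.  Pre-dose rows are always censored (no drug on
    board before the first dose).  Deterministic given ``seed``; each
    subject consumes an independent counter-derived substream so results do
    not depend on subject order.
    """
    design = design or TrialDesign()
    lloq = {a: units.ng_ml_to_nmol_l(design.lloq_ng_ml, a)
            for a in ("parent", "metabolite")}
    times = np.asarray(design.nominal_times, dtype=float)
    post = times > 0.0

    subjects, etas, thetas = [], [], []
    i = 0
    for dose_mg in sorted(design.arms):
        for _ in range(design.arms[dose_mg]):
            rng = np.random.default_rng([seed, i, 101])
            height = rng.uniform(*design.height_range)
            ppi = bool(rng.random() < design.ppi_prevalence)
            subj = Subject(id=f"S{i + 1:03d}", dose_mg=float(dose_mg),
                           height_cm=height, ppi=ppi)
            eta = sample_eta(model, 1, rng)[0]
            subjects.append(subj)
            etas.append(eta)
            thetas.append(individual_params(model, subj, eta))
            i += 1

    batch = pack_params(thetas)
    dose_umol = np.array([mg_to_umol(s.dose_mg) for s in subjects])
    dt = 0.02
    grid, c_par, c_met = solve_batch(batch, dose_umol, t_end=float(times[-1]), dt=dt)
    idx = np.rint(times / dt).astype(int)
    if not np.allclose(grid[idx], times):
        raise ValueError("nominal times must be multiples of the 0.02 h solver step")
    preds = {"parent": c_par[:, idx], "metabolite": c_met[:, idx]}

    rows = []
    for j, subj in enumerate(subjects):
        rng = np.random.default_rng([seed, j, 202])
        keep_post = (rng.random(post.sum()) >= design.missing_rate
                     if design.missing_rate > 0 else np.ones(post.sum(), bool))
        for dvid, analyte in _ANALYTE_OF_DVID.items():
            f = preds[analyte][j]
            y = f + rng.standard_normal(f.size) * _sd(f, analyte, model)
            keep = np.ones(times.size, bool)
            keep[post] = keep_post
            for k in np.nonzero(keep)[0]:
                cens = (times[k] <= 0.0) or (y[k] < lloq[analyte])
                rows.append((subj.id, subj.dose_mg, times[k], dvid,
                             np.nan if cens else y[k], int(cens),
                             lloq[analyte], subj.height_cm, int(subj.ppi)))

    obs = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    subj_df = pd.DataFrame({
        "ID": [s.id for s in subjects],
        "ARM_MG": [s.dose_mg for s in subjects],
        "HT_CM": [s.height_cm for s in subjects],
        "PPI": [int(s.ppi) for s in subjects],
    })
    truth = pd.DataFrame(
        {"ID": [s.id for s in subjects]}
        | {f"eta_{f}": np.array(etas)[:, k] for k, f in enumerate(ETA_FIELDS)}
        | {f"theta_{f}": [getattr(t, f) for t in thetas]
           for f in ("D50", "T1max", "dT2max", "CV1", "CV2", "V", "ke",
                     "pi1", "k12", "k21", "kmet")})
    return PKDataset(obs=obs, subjects=subj_df, truth=truth)


def _sd(pred, analyte, model):
    from .population import residual_sd
    return residual_sd(pred, analyte, model)


def design_summary(dataset: PKDataset) -> pd.DataFrame:
    """Per-arm observation and BLQ counts, per analyte.

    One row per (arm, analyte) with the total number of rows, the
    per-subject mean/min/max number of rows, and the number of
    left-censored (BLQ) rows.
    """
    obs = dataset.obs
    out = []
    arms = sorted(obs["ARM_MG"].unique()) if len(obs) else []
    for arm in arms:
        for dvid, analyte in _ANALYTE_OF_DVID.items():
            sub = obs[(obs["ARM_MG"] == arm) & (obs["DVID"] == dvid)]
            per = sub.groupby("ID").size()
            out.append({
                "arm_mg": arm, "analyte": analyte, "n_obs": len(sub),
                "per_subject_mean": float(per.mean()) if len(per) else 0.0,
                "per_subject_min": int(per.min()) if len(per) else 0,
                "per_subject_max": int(per.max()) if len(per) else 0,
                "n_blq": int(sub["CENS"].sum()),
            })
    cols = ["arm_mg", "analyte", "n_obs", "per_subject_mean",
            "per_subject_min", "per_subject_max", "n_blq"]
    return pd.DataFrame(out, columns=cols)
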
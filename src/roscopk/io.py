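"""Dataset and model-configuration readers/writers.

Datasets travel as long-format CSV with the columns of
:data:`roscopk.synthetic.DATASET_COLUMNS` (NONMEM-like: one row per
subject, time and analyte; DVID 1 = parent, 2 = metabolite; CENS 1 marks a
left-censored row, which must carry an empty DV and the LLOQ in effect).
Concentrations are nmol/L by default; ``units='ng_ml'`` converts on read
using the analyte-specific molar mass.  Models are flat YAML mappings with
the published parameter names; round trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import units as units_mod
from .population import PopulationModel, model_from_dict, model_to_dict
from .synthetic import DATASET_COLUMNS, DVID_METABOLITE, DVID_PARENT, PKDataset


def write_dataset(dataset: PKDataset, path) -> None:
    """Write the observation table as CSV (nmol/L, documented columns)."""
    dataset.obs.to_csv(path, index=False, float_format="%.10g")


def read_dataset(path, units: str = "nmol_l") -> PKDataset:
    """Read and validate a long-format concentration dataset.

    Validation is strict: unknown/missing columns, unknown DVID codes,
    duplicated (subject, time, analyte) keys, non-finite times, or a
    censored row carrying a concentration all raise ``ValueError`` listing
    the offending rows; nothing is silently coerced.
    """
    obs = pd.read_csv(path, dtype={"ID": str})
    for col, dt in (("ARM_MG", float), ("TIME_H", float), ("DVID", int),
                    ("DV_NMOL_L", float), ("CENS", int),
                    ("LLOQ_NMOL_L", float), ("HT_CM", float), ("PPI", int)):
        if col in obs.columns:
            obs[col] = obs[col].astype(dt)
    missing = [c for c in DATASET_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"dataset is missing columns {missing}")
    extra = [c for c in obs.columns if c not in DATASET_COLUMNS]
    if extra:
        raise ValueError(f"dataset has unknown columns {extra}")
    if units not in ("nmol_l", "ng_ml"):
        raise ValueError(f"units must be 'nmol_l' or 'ng_ml', got {units!r}")

    bad = ~obs["DVID"].isin([DVID_PARENT, DVID_METABOLITE])
    if bad.any():
        raise ValueError(f"unknown DVID codes at rows {list(obs.index[bad])}")
    if not obs["CENS"].isin([0, 1]).all():
        raise ValueError("CENS must be 0 or 1")
    cens = obs["CENS"] == 1
    has_dv = obs["DV_NMOL_L"].notna()
    conflict = cens & has_dv
    if conflict.any():
        raise ValueError(
            f"censored rows carry a concentration at rows {list(obs.index[conflict])}")
    blank = ~cens & ~has_dv
    if blank.any():
        raise ValueError(
            f"uncensored rows missing a concentration at rows {list(obs.index[blank])}")
    dup = obs.duplicated(subset=["ID", "TIME_H", "DVID"])
    if dup.any():
        raise ValueError(
            f"duplicate (ID, TIME_H, DVID) keys at rows {list(obs.index[dup])}")
    if not np.isfinite(obs["TIME_H"]).all():
        raise ValueError("non-finite times present")

    if units == "ng_ml":
        for dvid, analyte in ((DVID_PARENT, "parent"),
                              (DVID_METABOLITE, "metabolite")):
            sel = obs["DVID"] == dvid
            obs.loc[sel, "DV_NMOL_L"] = units_mod.ng_ml_to_nmol_l(
                obs.loc[sel, "DV_NMOL_L"], analyte)
            obs.loc[sel, "LLOQ_NMOL_L"] = units_mod.ng_ml_to_nmol_l(
                obs.loc[sel, "LLOQ_NMOL_L"], analyte)

    subj = (obs[["ID", "ARM_MG", "HT_CM", "PPI"]]
            .drop_duplicates(subset="ID").reset_index(drop=True))
    if len(subj) != obs["ID"].nunique():
        raise ValueError("inconsistent per-subject covariates")
    return PKDataset(obs=obs.reset_index(drop=True), subjects=subj)


def write_model(model: PopulationModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def read_model(path) -> PopulationModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
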
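"""Parameter registry: default calibration, JSON round-trip, input mapping.

The registry separates *calibration inputs* — the quantities a physiologist
would anchor from literature (basal pool sizes, basal fluxes, physiology
constants, feedback gains) — from the derived kinetic constants.  A full
22-parameter set is always produced by :func:`steatosim.model.calibrate_parameters`
so that the basal state is an exact steady state.

Default anchors describe a healthy-skewed reference subject: liver fat 3 %
of an 1,800 g liver, fasting plasma TG 100 mg/dL in 3 L of plasma, NEFA
delivery supplying 60 % of hepatic fatty-acid influx (DNL 17.5 %, plasma-TG
reuptake the remainder), VLDL-TG export of 15 g/day and dietary chylomicron
input of 70 g TG/day.
"""

from __future__ import annotations

import json
from pathlib import Path

from .model import (
    MW_TG,
    OX_KM_FRAC,
    U_DNL_FLOOR,
    PARAM_NAMES,
    BasalFluxAnchors,
    ModelParameters,
    calibrate_parameters,
)

__all__ = [
    "CALIBRATION_INPUT_NAMES",
    "DEFAULT_CALIBRATION_INPUTS",
    "default_parameters",
    "parameters_from_inputs",
    "inputs_from_parameters",
    "save_registry",
    "load_registry",
]

#: The 17 free calibration inputs; the remaining five rate constants
#: (k_ox, k_est_cyt, k_trans, k_est_er, k_clear) are pinned by the five
#: steady-state constraints.
CALIBRATION_INPUT_NAMES = (
    "fa_cyt_0", "tg_cyt_0", "fa_er_0", "tg_er_0", "tg_pl_0",
    "j_nefa", "j_dnl", "j_chylo",
    "v_lip_cyt", "v_lip_er", "v_vldl", "v_reuptake", "km_vldl",
    "m_liver", "v_pl",
    "gamma_up", "gamma_ox",
)

_M_LIVER = 1800.0      # g
_V_PL = 30.0           # dL (3 L plasma)
_LIVER_FAT_PCT = 3.0   # basal liver fat, % w/w
_PLASMA_TG = 100.0     # basal plasma TG, mg/dL
_TG_ER_0 = 1500.0      # µmol TG; small, fast-turnover VLDL-assembly pool

_TOTAL_LIVER_TG = _LIVER_FAT_PCT / 100.0 * _M_LIVER / (MW_TG * 1e-6)  # µmol

DEFAULT_CALIBRATION_INPUTS = {
    # pools (µmol)
    "fa_cyt_0": 10_000.0,
    "tg_cyt_0": _TOTAL_LIVER_TG - _TG_ER_0,
    "fa_er_0": 500.0,
    "tg_er_0": _TG_ER_0,
    "tg_pl_0": _PLASMA_TG * _V_PL / (MW_TG * 1e-3),
    # input fluxes (µmol FA/day except j_chylo in µmol TG/day)
    "j_nefa": 90_000.0,
    "j_dnl": 26_250.0,
    "j_chylo": 70.0 / (MW_TG * 1e-6),
    # basal internal-flux anchors (µmol TG/day)
    "v_lip_cyt": 30_000.0,
    "v_lip_er": 5_000.0,
    "v_vldl": 15.0 / (MW_TG * 1e-6),
    "v_reuptake": 11_250.0,
    "km_vldl": _TG_ER_0,  # half-saturated VLDL export at basal
    # physiology
    "m_liver": _M_LIVER,
    "v_pl": _V_PL,
    # feedback gains (the two free parameters; see docs/methods.md)
    "gamma_up": 0.2,
    "gamma_ox": 0.35,
}


def parameters_from_inputs(inputs: dict) -> ModelParameters:
    """Calibrate a full 22-parameter set from the 17 calibration inputs."""
    missing = set(CALIBRATION_INPUT_NAMES) - set(inputs)
    if missing:
        raise ValueError(f"missing calibration inputs: {sorted(missing)}")
    pools = {k: float(inputs[k]) for k in
             ("fa_cyt_0", "tg_cyt_0", "fa_er_0", "tg_er_0", "tg_pl_0")}
    anchors = BasalFluxAnchors(
        j_nefa=float(inputs["j_nefa"]),
        j_dnl=float(inputs["j_dnl"]),
        j_chylo=float(inputs["j_chylo"]),
        v_lip_cyt=float(inputs["v_lip_cyt"]),
        v_lip_er=float(inputs["v_lip_er"]),
        v_vldl=float(inputs["v_vldl"]),
        v_reuptake=float(inputs["v_reuptake"]),
        km_vldl=float(inputs["km_vldl"]),
        v_ox=float(inputs["v_ox"]) if "v_ox" in inputs else None,
    )
    return calibrate_parameters(
        pools, anchors,
        m_liver=float(inputs["m_liver"]), v_pl=float(inputs["v_pl"]),
        gamma_up=float(inputs["gamma_up"]), gamma_ox=float(inputs["gamma_ox"]),
    )


def inputs_from_parameters(params: ModelParameters) -> dict:
    """Recover the calibration inputs implied by a full parameter set."""
    return {
        "fa_cyt_0": params.fa_cyt_0, "tg_cyt_0": params.tg_cyt_0,
        "fa_er_0": params.fa_er_0, "tg_er_0": params.tg_er_0,
        "tg_pl_0": params.tg_pl_0,
        "j_nefa": params.j_nefa, "j_dnl": params.j_dnl, "j_chylo": params.j_chylo,
        "v_lip_cyt": params.k_lip_cyt * params.tg_cyt_0,
        "v_lip_er": params.k_lip_er * params.tg_er_0,
        "v_vldl": params.vmax_vldl * params.tg_er_0 / (params.km_vldl + params.tg_er_0),
        "v_reuptake": params.k_reuptake * params.tg_pl_0,
        "km_vldl": params.km_vldl,
        "m_liver": params.m_liver, "v_pl": params.v_pl,
        "gamma_up": params.gamma_up, "gamma_ox": params.gamma_ox,
    }


def default_parameters() -> ModelParameters:
    """The base 22-parameter registry calibrated from the default anchors."""
    return parameters_from_inputs(DEFAULT_CALIBRATION_INPUTS)


def save_registry(params: ModelParameters, path) -> None:
    """Write the registry JSON: 22 parameters + constants + anchor block."""
    payload = {
        "parameters": params.as_dict(),
        "constants": {
            "mw_tg": MW_TG,
            "ox_km_frac": OX_KM_FRAC,
            "u_dnl_floor": U_DNL_FLOOR,
        },
        "anchors": inputs_from_parameters(params),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_registry(path) -> ModelParameters:
    payload = json.loads(Path(path).read_text())
    if set(payload["parameters"]) != set(PARAM_NAMES):
        raise ValueError(
            "registry parameter block must contain exactly the "
            f"{len(PARAM_NAMES)} model parameters"
        )
    return ModelParameters.from_dict(payload["parameters"])
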
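"""Phenomenological cardiac action-potential models.

Each model describes a dimensionless transmembrane voltage ``u`` obeying

    du/dt = I_tot(u, gates; params) + I_stim(t)

together with one to three gating/recovery variables, so the state dimension
ranges from two to four.  Six models are provided:

====== ====================================== ====== =======
name   origin                                 states params
====== ====================================== ====== =======
MS     Mitchell & Schaeffer (2003)                 2       5
MMS    modified MS, Corrado & Niederer (2016)      2       5
MFHN   modified FitzHugh-Nagumo,                   2       5
       Rogers & McCulloch (1994)
FK     Fenton & Karma (1998), three-current        3      13
BOCF   Bueno-Orovio, Cherry & Fenton (2008)        4      27
       minimal human ventricular model
BBOCF  Brugada-variant BOCF with voltage-          4      33
       dependent tau_w+ and s-dependent tau_si
====== ====================================== ====== =======

Time constants are in milliseconds, rates in 1/ms, and voltages are
dimensionless.  Defaults follow the original publications (FK uses the
Beeler-Reuter-derived parameter set; BOCF the epicardial set with the
constant offset u_o fixed at 0 so that 27 parameters are fittable).  The
BBOCF defaults make its two split time scales degenerate, so out of the box
it reproduces the BOCF epicardial dynamics; the split parameters give the
fitter the freedom needed for saddleback ("Brugada-phenotype") morphologies.

Heaviside convention: every gating regime switches when the voltage reaches
its threshold, i.e. the "active"/suprathreshold branch applies for
``u >= threshold`` (H(0) = 1).  This matters only on a measure-zero set but
is applied consistently here and in the batch integration kernels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "Parameter",
    "ModelSpec",
    "MODEL_NAMES",
    "get_model",
    "list_parameters",
    "parameter_table",
    "export_parameters",
    "model_rhs",
    "rest_state",
]


@dataclass(frozen=True)
class Parameter:
    """One model constant: name, default value and default fitting bounds."""

    name: str
    default: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ConfigurationError(
                f"parameter {self.name!r}: lower bound {self.lower} must be "
                f"smaller than upper bound {self.upper}"
            )
        if not (self.lower <= self.default <= self.upper):
            raise ConfigurationError(
                f"parameter {self.name!r}: default {self.default} outside "
                f"bounds [{self.lower}, {self.upper}]"
            )


@dataclass(frozen=True)
class ModelSpec:
    """A model's roster: state dimension, parameters and scales.

    ``default_normalization`` is the recommended value of the "normalize to"
    setting when fitting data with this model (0 would bypass
    normalization).  The BOCF-family peak voltage overshoots 1 (u_u = 1.55),
    so data are normalized to 1.35 for those models by default, in line with
    the values used for published fits (1.3-1.4 depending on the dataset).

    ``rest_state_default`` is the analytic resting equilibrium under the
    default parameters; use :func:`rest_state` for arbitrary parameters.
    """

    name: str
    state_dim: int
    parameters: tuple[Parameter, ...]
    default_normalization: float
    rest_state_default: tuple[float, ...] = field(repr=False)

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters)

    @property
    def defaults(self) -> np.ndarray:
        return np.array([p.default for p in self.parameters])

    @property
    def lower(self) -> np.ndarray:
        return np.array([p.lower for p in self.parameters])

    @property
    def upper(self) -> np.ndarray:
        return np.array([p.upper for p in self.parameters])

    def index(self, name: str) -> int:
        try:
            return self.parameter_names.index(name)
        except ValueError:
            raise ConfigurationError(
                f"model {self.name} has no parameter {name!r}"
            ) from None


def _P(*rows: tuple[str, float, float, float]) -> tuple[Parameter, ...]:
    return tuple(Parameter(*row) for row in rows)


# --- rosters -----------------------------------------------------------------

_MS_PARAMS = _P(
    ("tau_in", 0.3, 0.05, 1.0),
    ("tau_out", 6.0, 1.0, 20.0),
    ("tau_open", 120.0, 50.0, 400.0),
    ("tau_close", 150.0, 50.0, 400.0),
    ("v_gate", 0.13, 0.05, 0.3),
)

_MMS_PARAMS = _MS_PARAMS  # same roster; the cubic source term differs

_MFHN_PARAMS = _P(
    ("a", 0.13, 0.05, 0.3),
    ("b", 0.013, 0.005, 0.05),
    ("c1", 0.26, 0.1, 1.0),
    ("c2", 0.1, 0.02, 0.5),
    ("d", 1.0, 0.3, 3.0),
)

_FK_PARAMS = _P(
    ("tau_d", 0.25, 0.05, 1.0),
    ("tau_r", 33.33, 10.0, 130.0),
    ("tau_si", 29.0, 10.0, 127.0),
    ("tau_0", 12.5, 1.0, 50.0),
    ("tau_vp", 3.33, 1.0, 20.0),
    ("tau_v1m", 1250.0, 50.0, 2000.0),
    ("tau_v2m", 19.6, 5.0, 100.0),
    ("tau_wp", 870.0, 100.0, 2000.0),
    ("tau_wm", 41.0, 10.0, 200.0),
    ("u_c", 0.13, 0.05, 0.3),
    ("u_v", 0.04, 0.005, 0.1),
    ("u_csi", 0.85, 0.2, 0.95),
    ("k", 10.0, 5.0, 20.0),
)

_BOCF_PARAMS = _P(
    ("u_u", 1.55, 1.0, 2.0),
    ("theta_v", 0.3, 0.1, 0.5),
    ("theta_w", 0.13, 0.05, 0.5),
    ("theta_vm", 0.006, 0.001, 0.05),
    ("theta_o", 0.006, 0.001, 0.05),
    ("tau_v1m", 60.0, 10.0, 500.0),
    ("tau_v2m", 1150.0, 100.0, 2000.0),
    ("tau_vp", 1.4506, 0.5, 10.0),
    ("tau_w1m", 60.0, 10.0, 300.0),
    ("tau_w2m", 15.0, 5.0, 200.0),
    ("k_wm", 65.0, 10.0, 200.0),
    ("u_wm", 0.03, 0.005, 0.2),
    ("tau_wp", 200.0, 50.0, 1000.0),
    ("tau_fi", 0.11, 0.05, 0.5),
    ("tau_o1", 400.0, 50.0, 500.0),
    ("tau_o2", 6.0, 1.0, 50.0),
    ("tau_so1", 30.0181, 10.0, 100.0),
    ("tau_so2", 0.9957, 0.5, 10.0),
    ("k_so", 2.0458, 1.0, 10.0),
    ("u_so", 0.65, 0.3, 1.0),
    ("tau_s1", 2.7342, 1.0, 20.0),
    ("tau_s2", 16.0, 2.0, 50.0),
    ("k_s", 2.0994, 1.0, 10.0),
    ("u_s", 0.9087, 0.5, 1.2),
    ("tau_si", 1.8875, 0.5, 10.0),
    ("tau_winf", 0.07, 0.01, 0.3),
    ("w_infstar", 0.94, 0.5, 1.0),
)

# BBOCF: tau_wp -> sigmoidal blend tau_w1p/tau_w2p, tau_si -> tau_si1/tau_si2
_BBOCF_PARAMS = tuple(
    [p for p in _BOCF_PARAMS if p.name not in ("tau_wp", "tau_si")]
    + list(
        _P(
            ("tau_w1p", 200.0, 50.0, 1000.0),
            ("tau_w2p", 200.0, 50.0, 1000.0),
            ("k_wp", 8.0, 1.0, 100.0),
            ("u_wp", 0.5, 0.01, 1.0),
            ("tau_si1", 1.8875, 0.5, 10.0),
            ("tau_si2", 1.8875, 0.5, 10.0),
            ("k_si", 20.0, 1.0, 100.0),
            ("s_c", 0.5, 0.01, 1.0),
        )
    )
)


def _bocf_rest_s(k_s: float, u_s: float) -> float:
    # steady state of the s gate at u = 0
    return (1.0 + math.tanh(-k_s * u_s)) / 2.0


_REGISTRY: dict[str, ModelSpec] = {}


def _register(spec: ModelSpec) -> ModelSpec:
    _REGISTRY[spec.name] = spec
    return spec


MS = _register(ModelSpec("MS", 2, _MS_PARAMS, 1.0, (0.0, 1.0)))
MMS = _register(ModelSpec("MMS", 2, _MMS_PARAMS, 1.0, (0.0, 1.0)))
MFHN = _register(ModelSpec("MFHN", 2, _MFHN_PARAMS, 1.0, (0.0, 0.0)))
def _fk_rest_u(tau_si: float, tau_0: float, u_csi: float, k: float) -> float:
    u = 0.0
    for _ in range(50):
        u_new = tau_0 * (1.0 + math.tanh(k * (u - u_csi))) / (2.0 * tau_si)
        if abs(u_new - u) < 1e-16:
            return u_new
        u = u_new
    return u


FK = _register(
    ModelSpec("FK", 3, _FK_PARAMS, 1.0, (_fk_rest_u(29.0, 12.5, 0.85, 10.0), 1.0, 1.0))
)
BOCF = _register(
    ModelSpec("BOCF", 4, _BOCF_PARAMS, 1.35, (0.0, 1.0, 1.0, _bocf_rest_s(2.0994, 0.9087)))
)
BBOCF = _register(
    ModelSpec("BBOCF", 4, _BBOCF_PARAMS, 1.35, (0.0, 1.0, 1.0, _bocf_rest_s(2.0994, 0.9087)))
)

MODEL_NAMES = tuple(_REGISTRY)


def get_model(name: str) -> ModelSpec:
    """Look up a model by name (case-insensitive)."""
    spec = _REGISTRY.get(str(name).upper())
    if spec is None:
        raise ConfigurationError(
            f"unknown model {name!r}; available models: {', '.join(MODEL_NAMES)}"
        )
    return spec


def list_parameters(model: ModelSpec | str) -> list[tuple[str, float, float, float]]:
    """Ordered (name, default, lower, upper) rows for a model's roster."""
    spec = get_model(model) if isinstance(model, str) else model
    return [(p.name, p.default, p.lower, p.upper) for p in spec.parameters]


def parameter_table(model: ModelSpec | str) -> pd.DataFrame:
    spec = get_model(model) if isinstance(model, str) else model
    return pd.DataFrame(
        list_parameters(spec), columns=["name", "default", "lower", "upper"]
    )


def export_parameters(model: ModelSpec | str, path: str) -> None:
    """Write the roster as CSV or JSON depending on the file extension."""
    spec = get_model(model) if isinstance(model, str) else model
    table = parameter_table(spec)
    if str(path).endswith(".json"):
        with open(path, "w") as fh:
            json.dump(table.to_dict(orient="records"), fh, indent=1)
    else:
        table.to_csv(path, index=False)


def rest_state(model: ModelSpec | str, params: np.ndarray | None = None) -> np.ndarray:
    """Analytic resting equilibrium (u = 0, gates at their u=0 steady state)."""
    spec = get_model(model) if isinstance(model, str) else model
    params = _check_params(spec, params)
    if spec.name in ("MS", "MMS"):
        return np.array([0.0, 1.0])
    if spec.name == "MFHN":
        return np.array([0.0, 0.0])
    if spec.name == "FK":
        # The slow-inward tanh has a tiny tail at u = 0, so the exact rest
        # voltage is the fixed point of
        # u = tau_0 * (1 + tanh(k(u - u_csi)))/(2 tau_si), of order 1e-8
        # for the defaults.
        u = _fk_rest_u(
            params[spec.index("tau_si")],
            params[spec.index("tau_0")],
            params[spec.index("u_csi")],
            params[spec.index("k")],
        )
        return np.array([u, 1.0, 1.0])
    # BOCF / BBOCF: the s gate relaxes to its sigmoidal steady state at u=0
    k_s = params[spec.index("k_s")]
    u_s = params[spec.index("u_s")]
    return np.array([0.0, 1.0, 1.0, _bocf_rest_s(k_s, u_s)])


def _check_params(spec: ModelSpec, params: np.ndarray | None) -> np.ndarray:
    if params is None:
        return spec.defaults
    params = np.asarray(params, dtype=float)
    if params.shape != (spec.n_parameters,):
        raise ConfigurationError(
            f"model {spec.name} expects {spec.n_parameters} parameters, "
            f"got shape {params.shape}"
        )
    return params


def _H(x: float) -> float:
    """Heaviside step, H(0) = 1."""
    return 1.0 if x >= 0.0 else 0.0


def model_rhs(
    model: ModelSpec | str,
    state: np.ndarray,
    params: np.ndarray | None = None,
    i_stim: float = 0.0,
) -> np.ndarray:
    """Time derivative of the model state; du/dt = I_tot + i_stim.

    This is the plain reference implementation of each right-hand side,
    independent of the compiled batch kernels in :mod:`cardioswarm._kernels`;
    the two are cross-checked against each other in the test suite.
    """
    spec = get_model(model) if isinstance(model, str) else model
    params = _check_params(spec, params)
    state = np.asarray(state, dtype=float)
    if state.shape != (spec.state_dim,):
        raise ConfigurationError(
            f"model {spec.name} has state dimension {spec.state_dim}, "
            f"got shape {state.shape}"
        )
    return _RHS[spec.name](state, params, float(i_stim))


def _rhs_ms(state, p, i_stim):
    u, h = state
    tau_in, tau_out, tau_open, tau_close, v_gate = p
    du = h * u * u * (1.0 - u) / tau_in - u / tau_out + i_stim
    dh = -h / tau_close if u >= v_gate else (1.0 - h) / tau_open
    return np.array([du, dh])


def _rhs_mms(state, p, i_stim):
    # Corrado-Niederer variant: cubic source with explicit activation
    # threshold and an h-weighted outward current (vanishes at full rest).
    u, h = state
    tau_in, tau_out, tau_open, tau_close, v_gate = p
    du = h * u * (u - v_gate) * (1.0 - u) / tau_in - (1.0 - h) * u / tau_out + i_stim
    dh = -h / tau_close if u >= v_gate else (1.0 - h) / tau_open
    return np.array([du, dh])


def _rhs_mfhn(state, p, i_stim):
    u, v = state
    a, b, c1, c2, d = p
    du = c1 * u * (u - a) * (1.0 - u) - c2 * u * v + i_stim
    dv = b * (u - d * v)
    return np.array([du, dv])


def _rhs_fk(state, p, i_stim):
    u, v, w = state
    (tau_d, tau_r, tau_si, tau_0, tau_vp, tau_v1m, tau_v2m,
     tau_wp, tau_wm, u_c, u_v, u_csi, k) = p
    pgate = _H(u - u_c)
    q = _H(u - u_v)
    j_fi = -v * pgate * (1.0 - u) * (u - u_c) / tau_d
    j_so = u * (1.0 - pgate) / tau_0 + pgate / tau_r
    j_si = -w * (1.0 + math.tanh(k * (u - u_csi))) / (2.0 * tau_si)
    tau_vm = q * tau_v1m + (1.0 - q) * tau_v2m
    du = -(j_fi + j_so + j_si) + i_stim
    dv = (1.0 - pgate) * (1.0 - v) / tau_vm - pgate * v / tau_vp
    dw = (1.0 - pgate) * (1.0 - w) / tau_wm - pgate * w / tau_wp
    return np.array([du, dv, dw])


def _bocf_core(state, c, i_stim):
    """Shared BOCF/BBOCF right-hand side.

    ``c`` is a dict of constants where tau_wp and tau_si are already the
    (possibly state-dependent) effective values.
    """
    u, v, w, s = state
    hv = _H(u - c["theta_v"])
    hw = _H(u - c["theta_w"])
    hvm = _H(u - c["theta_vm"])
    ho = _H(u - c["theta_o"])
    tau_vm = (1.0 - hvm) * c["tau_v1m"] + hvm * c["tau_v2m"]
    tau_wm = c["tau_w1m"] + (c["tau_w2m"] - c["tau_w1m"]) * (
        1.0 + math.tanh(c["k_wm"] * (u - c["u_wm"]))
    ) / 2.0
    tau_so = c["tau_so1"] + (c["tau_so2"] - c["tau_so1"]) * (
        1.0 + math.tanh(c["k_so"] * (u - c["u_so"]))
    ) / 2.0
    tau_s = (1.0 - hw) * c["tau_s1"] + hw * c["tau_s2"]
    tau_o = (1.0 - ho) * c["tau_o1"] + ho * c["tau_o2"]
    v_inf = 1.0 if u < c["theta_vm"] else 0.0
    w_inf = (1.0 - ho) * (1.0 - u / c["tau_winf"]) + ho * c["w_infstar"]
    j_fi = -v * hv * (u - c["theta_v"]) * (c["u_u"] - u) / c["tau_fi"]
    j_so = u * (1.0 - hw) / tau_o + hw / tau_so  # u_o fixed at 0
    j_si = -hw * w * s / c["tau_si"]
    du = -(j_fi + j_so + j_si) + i_stim
    dv = (1.0 - hv) * (v_inf - v) / tau_vm - hv * v / c["tau_vp"]
    dw = (1.0 - hw) * (w_inf - w) / tau_wm - hw * w / c["tau_wp"]
    ds = ((1.0 + math.tanh(c["k_s"] * (u - c["u_s"]))) / 2.0 - s) / tau_s
    return np.array([du, dv, dw, ds])


def _rhs_bocf(state, p, i_stim):
    c = dict(zip(BOCF.parameter_names, p))
    return _bocf_core(state, c, i_stim)


def _rhs_bbocf(state, p, i_stim):
    c = dict(zip(BBOCF.parameter_names, p))
    u, _, _, s = state
    c["tau_wp"] = c["tau_w1p"] + (c["tau_w2p"] - c["tau_w1p"]) * (
        1.0 + math.tanh(c["k_wp"] * (u - c["u_wp"]))
    ) / 2.0
    c["tau_si"] = c["tau_si1"] + (c["tau_si2"] - c["tau_si1"]) * (
        1.0 + math.tanh(c["k_si"] * (s - c["s_c"]))
    ) / 2.0
    return _bocf_core(state, c, i_stim)


_RHS = {
    "MS": _rhs_ms,
    "MMS": _rhs_mms,
    "MFHN": _rhs_mfhn,
    "FK": _rhs_fk,
    "BOCF": _rhs_bocf,
    "BBOCF": _rhs_bbocf,
}
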
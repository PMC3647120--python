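"""Configuration loading, defaults and resolved-parameter dumps.

Configuration files are flat YAML key-value mappings.  Unknown keys and
non-numeric values are rejected with an error listing the offenders.  The
defaults reproduce the shipped single-neuron parameter table and the
network/mean-field reference setting; derived conductances (g_IS = alpha*g_SI
etc.) and characteristic time constants are computed and included in the
resolved dump.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .compartmental import NeuronParams
from .meanfield import MeanFieldParams
from .network import NetworkParams
from .reduced import GEOMETRIES, DendriticConfig, shunting_strength, tau_soma
from .synapses import SynapseParams


class ConfigError(ValueError):
    """Raised for malformed configuration files."""


_NEURON_KEYS = {
    "E_L", "E_E", "E_I", "C_S", "C_D", "g_S", "g_D",
    "g_SI", "g_SE", "g_IE", "alpha", "g_IS", "g_ES", "g_EI",
}
_GEOMETRY_KEYS = {"geometry", "N"}
_SYNAPSE_KEYS = {"tau_E", "tau_I", "w_E", "w_I"}
_NETWORK_KEYS = {
    "N_E", "N_I", "p", "C_S_E", "C_S_I", "E_thres", "E_reset",
    "sigma", "g_ext", "g_ES_net", "stim_on", "stim_off", "stim_target",
    "dt", "fixed_in_degree",
}
_MEANFIELD_KEYS = {"mu_E", "mu_I", "beta_rate", "a", "b", "c", "d"}
_ALL_KEYS = _NEURON_KEYS | _GEOMETRY_KEYS | _SYNAPSE_KEYS | _NETWORK_KEYS | _MEANFIELD_KEYS

_STRING_KEYS = {"geometry", "stim_target"}
_BOOL_KEYS = {"fixed_in_degree"}


@dataclass(frozen=True)
class Config:
    """Resolved parameter bundle for all modules."""

    neuron: NeuronParams
    dendritic: DendriticConfig
    syn_E: SynapseParams
    syn_I: SynapseParams
    network: NetworkParams
    meanfield: MeanFieldParams
    raw: dict


def _validate(raw: dict) -> None:
    unknown = sorted(set(raw) - _ALL_KEYS)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
    bad = []
    for key, value in raw.items():
        if key in _STRING_KEYS:
            if not isinstance(value, str):
                bad.append(key)
        elif key in _BOOL_KEYS:
            if not isinstance(value, bool):
                bad.append(key)
        elif isinstance(value, bool) or not isinstance(value, (int, float)):
            bad.append(key)
    if bad:
        raise ConfigError(f"non-numeric or mistyped values for keys: {', '.join(sorted(bad))}")
    if "geometry" in raw and raw["geometry"] not in GEOMETRIES:
        raise ConfigError(f"geometry must be one of {GEOMETRIES}")


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> Config:
    """Load a flat YAML configuration; missing keys fall back to defaults."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("configuration must be a flat key-value mapping")
        raw.update(loaded)
    if overrides:
        raw.update(overrides)
    _validate(raw)

    def pick(keys, **renames):
        out = {k: raw[k] for k in keys if k in raw}
        for src, dst in renames.items():
            if src in out:
                out[dst] = out.pop(src)
        return out

    try:
        neuron = NeuronParams(**pick(_NEURON_KEYS))
        dendritic = DendriticConfig(
            geometry=raw.get("geometry", "on_path"), N=int(raw.get("N", 1))
        )
        syn_E = SynapseParams(tau=raw.get("tau_E", 100.0), w=raw.get("w_E", 24.0))
        syn_I = SynapseParams(tau=raw.get("tau_I", 10.0), w=raw.get("w_I", 2.0))
        net_kwargs = pick(_NETWORK_KEYS - {"stim_on", "stim_off"}, g_ES_net="g_ES")
        net_kwargs["N_E"] = int(net_kwargs.get("N_E", 2000))
        net_kwargs["N_I"] = int(net_kwargs.get("N_I", 500))
        if "stim_on" in raw or "stim_off" in raw:
            net_kwargs["stim_window"] = (raw.get("stim_on", 50.0), raw.get("stim_off", 250.0))
        for k in ("tau_E", "tau_I", "w_E", "w_I"):
            if k in raw:
                net_kwargs[k] = raw[k]
        network = NetworkParams(**net_kwargs)
        mf_kwargs = pick(_MEANFIELD_KEYS, beta_rate="beta")
        for k in ("w_E", "w_I", "tau_E", "tau_I", "p"):
            if k in raw:
                mf_kwargs[k] = raw[k]
        mf_kwargs["N_E"] = network.N_E
        mf_kwargs["N_I"] = network.N_I
        mf_kwargs.setdefault("kappa_G", 1.0 / (neuron.E_L - neuron.E_I))
        meanfield = MeanFieldParams(**mf_kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    return Config(
        neuron=neuron, dendritic=dendritic, syn_E=syn_E, syn_I=syn_I,
        network=network, meanfield=meanfield, raw=dict(raw),
    )


def resolved_dump(config: Config) -> dict:
    """All effective parameters including derived quantities, YAML-ready."""
    n = config.neuron
    d = config.dendritic
    net = config.network
    mf = config.meanfield
    dump = {
        "E_L": n.E_L, "E_E": n.E_E, "E_I": n.E_I,
        "C_S": n.C_S, "C_D": n.C_D, "g_S": n.g_S, "g_D": n.g_D,
        "g_SI": n.g_SI, "g_SE": n.g_SE, "g_IE": n.g_IE, "alpha": n.alpha,
        "g_IS": n.g_IS, "g_ES": n.g_ES, "g_EI": n.g_EI,
        "tau_S_on_path": n.tau_S, "tau_DI": n.tau_DI, "tau_DE": n.tau_DE,
        "geometry": d.geometry, "N": d.N,
        "tau_S_geometry": tau_soma(n, d),
        "kappa_geometry": shunting_strength(n, d),
        "kappa_G": 1.0 / (n.E_L - n.E_I),
        "tau_E": config.syn_E.tau, "w_E": config.syn_E.w,
        "tau_I": config.syn_I.tau, "w_I": config.syn_I.w,
        "N_E": net.N_E, "N_I": net.N_I, "p": net.p,
        "C_S_E": net.C_S_E, "C_S_I": net.C_S_I,
        "E_thres": net.E_thres, "E_reset": net.E_reset,
        "sigma": net.sigma, "g_ext": net.g_ext, "g_ES_net": net.g_ES,
        "stim_on": net.stim_window[0], "stim_off": net.stim_window[1],
        "stim_target": net.stim_target, "dt": net.dt,
        "mu_E": mf.mu_E, "mu_I": mf.mu_I, "beta_rate": mf.beta,
        "a": mf.a, "b": mf.b, "c": mf.c, "d": mf.d,
    }
    return dump


def write_resolved(config: Config, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(resolved_dump(config), sort_keys=False))
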
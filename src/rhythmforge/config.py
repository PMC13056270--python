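"""YAML configuration: flat dotted keys (``neuron.tau_m: 12``) or nested maps.

Recognized namespaces: ``neuron.*`` (LIFParams fields, plus ``weight`` as an
alias for ``w``), ``cricket.*`` (CricketParams fields; ``cricket.prc.*`` for
the PRC shape), and ``sweep.*`` (SweepConfig scalars such as ``n_intervals``,
``discard``, ``intrinsic_rate``, ``phase_offset``).
"""

from __future__ import annotations

from dataclasses import asdict, replace
from pathlib import Path

import yaml

from .cricket import CricketParams, PRCSpec
from .errors import InvalidParameterError
from .lif import LIFParams

_NEURON_ALIASES = {"weight": "w"}


def _flatten(d: dict, prefix: str = "") -> dict[str, object]:
    out: dict[str, object] = {}
    for key, value in d.items():
        full = f"{prefix}{key}"
        if isinstance(value, dict):
            out.update(_flatten(value, full + "."))
        else:
            out[full] = value
    return out


def load_config(path: str | Path | None) -> dict[str, object]:
    """Load a YAML config into a flat dotted-key dict (empty if path is None)."""
    if path is None:
        return {}
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InvalidParameterError("config file must contain a mapping")
    return _flatten(raw)


def apply_config(
    flat: dict[str, object],
    neuron: LIFParams | None = None,
    cricket: CricketParams | None = None,
) -> tuple[LIFParams, CricketParams, dict[str, object]]:
    """Apply flat config keys; returns (neuron, cricket, leftover sweep keys)."""
    neuron = neuron or LIFParams()
    cricket = cricket or CricketParams()
    neuron_kw: dict[str, object] = {}
    cricket_kw: dict[str, object] = {}
    prc_kw: dict[str, object] = {}
    sweep_kw: dict[str, object] = {}
    for key, value in flat.items():
        ns, _, rest = key.partition(".")
        if ns == "neuron":
            neuron_kw[_NEURON_ALIASES.get(rest, rest)] = value
        elif ns == "cricket":
            if rest.startswith("prc."):
                prc_kw[rest[4:]] = value
            else:
                cricket_kw[rest] = value
        elif ns == "sweep":
            sweep_kw[rest] = value
        else:
            raise InvalidParameterError(f"unknown config key {key!r}")
    try:
        if neuron_kw:
            neuron = replace(neuron, **neuron_kw)
        if prc_kw:
            cricket_kw["prc"] = replace(cricket.prc, **prc_kw)
        if cricket_kw:
            cricket = replace(cricket, **cricket_kw)
    except TypeError as exc:
        raise InvalidParameterError(str(exc)) from exc
    return neuron, cricket, sweep_kw


def dump_resolved(path: str | Path, neuron: LIFParams, cricket: CricketParams, extra: dict) -> None:
    """Write the fully resolved configuration next to a run's outputs."""
    doc = {"neuron": asdict(neuron), "cricket": asdict(cricket), **extra}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
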
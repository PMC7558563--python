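"""Plain-text scenario configuration.

A scenario file is a flat ``key = value`` listing (``#`` starts a comment)
mirroring the exposure-table columns::

    label = NC-4
    icl = 1.08          # clo
    rt_static = 0.0421  # m2.kPa/W
    imt = 0.37
    ta = 40             # degC
    pw = 3.3            # kPa
    va = 0.33           # m/s
    vw = 1.25           # m/s, measured walking speed (optional)
    met = 155           # W/m2
    duration = 70       # min
    height = 1.78       # m
    weight = 80         # kg
"""

from __future__ import annotations

from pathlib import Path

from .clothing import ClothingEnsemble
from .phs import ScenarioInput, Subject

_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def parse_kv(text: str) -> dict[str, str]:
    """Parse ``key = value`` lines, ignoring blanks and ``#`` comments."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key.lower()] = value
    return out


def scenario_from_text(text: str) -> ScenarioInput:
    kv = parse_kv(text)

    def fget(key: str, default=None):
        if key in kv:
            return float(kv[key])
        if default is None:
            raise KeyError(f"missing required scenario key {key!r}")
        return default

    ens = ClothingEnsemble(
        icl=fget("icl"),
        rt_static=fget("rt_static"),
        imt=fget("imt"),
        pr=fget("pr", 1.0),
        label=kv.get("label", ""),
    )
    subject = Subject(
        height=fget("height", 1.8),
        weight=fget("weight", 75.0),
        acclimatized=_BOOL[kv.get("acclimatized", "false").lower()],
        drink_allowed=_BOOL[kv.get("drink", "true").lower()],
    )
    return ScenarioInput(
        label=kv.get("label", "scenario"),
        ensemble=ens,
        ta=fget("ta"),
        tr=float(kv["tr"]) if "tr" in kv else None,
        pw=fget("pw"),
        va=fget("va"),
        met=fget("met"),
        duration=int(fget("duration", 70)),
        vw_measured=float(kv["vw"]) if "vw" in kv else None,
        subject=subject,
    )


def load_scenario(path: str | Path) -> ScenarioInput:
    """Read one scenario from a plain-text config file."""
    return scenario_from_text(Path(path).read_text())
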
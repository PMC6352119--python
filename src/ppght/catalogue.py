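"""The 125-entry morphological feature catalogue.

Seven categories with fixed sizes:

====================  =====
time_span             23
ppg_amplitude         14
vpg_apg               10
waveform_area         4
power_area            15
ratio                 43
slope                 16
====================  =====

Each entry is a :class:`FeatureDefinition` naming a kernel and its landmark
operands.  The canonical list ships as ``data/catalogue.json`` (the source of
truth at run time); :func:`build_default_catalogue` regenerates it and is kept
in lock-step by the test suite.

Naming scheme (ASCII, CSV-safe):

- ``span_O_S``            time from O to S, ms
- ``amp_c-2``             PPG value at the APG c-wave time, onset-corrected
- ``val_w``               VPG value at the w wave (derivative levels baseline 0)
- ``area_O_S``            trapezoidal PPG area O→S, a.u.·s
- ``pow_S+1_c-1``         sum of squared VPG samples over [t_S, t_c]
- ``slope_b-2_d-2``       PPG chord slope between the b- and d-wave times
- ``X__over__Y``          ratio of two kernel values
- ``val_b-c-d__over__val_a``  APG combination (b−c−d)/a
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from ._tokens import parse_token

CATEGORY_SIZES = {
    "time_span": 23,
    "ppg_amplitude": 14,
    "vpg_apg": 10,
    "waveform_area": 4,
    "power_area": 15,
    "ratio": 43,
    "slope": 16,
}

TOTAL_FEATURES = 125


@dataclass(frozen=True)
class FeatureDefinition:
    name: str
    category: str
    kernel: str
    operands: dict = field(default_factory=dict)
    note: str = ""


def _span(f1, f2):
    return {"kernel": "span", "operands": {"f1": f1, "f2": f2}}


def _amp(tok):
    return {"kernel": "amp", "operands": {"token": tok}}


def _val(tok):
    return {"kernel": "val", "operands": {"token": tok}}


def _area(f1, f2):
    return {"kernel": "area", "operands": {"f1": f1, "f2": f2}}


def _pow(f1, f2):
    return {"kernel": "pow", "operands": {"f1": f1, "f2": f2}}


def _slope(f1, f2):
    return {"kernel": "slope", "operands": {"f1": f1, "f2": f2}}


def _combo(terms):
    # signed APG combination: first term minus the rest, e.g. b − c − d
    return {"kernel": "apg_combo", "operands": {"terms": terms}}


def _kernel_name(spec: dict) -> str:
    k, op = spec["kernel"], spec["operands"]
    if k == "span":
        return f"span_{op['f1']}_{op['f2']}"
    if k == "amp":
        return f"amp_{op['token']}"
    if k == "val":
        return f"val_{op['token']}"
    if k == "area":
        return f"area_{op['f1']}_{op['f2']}"
    if k == "pow":
        return f"pow_{op['f1']}_{op['f2']}"
    if k == "slope":
        return f"slope_{op['f1']}_{op['f2']}"
    if k == "apg_combo":
        return f"val_{'-'.join(op['terms'])}"
    raise ValueError(k)


def _entry(category: str, spec: dict, note: str = "") -> FeatureDefinition:
    return FeatureDefinition(_kernel_name(spec), category, spec["kernel"], spec["operands"], note)


def _ratio(category: str, num: dict, den: dict, note: str = "") -> FeatureDefinition:
    name = f"{_kernel_name(num)}__over__{_kernel_name(den)}"
    return FeatureDefinition(name, category, "ratio", {"num": num, "den": den}, note)


def build_default_catalogue() -> list[FeatureDefinition]:
    """Construct the canonical 125-entry catalogue programmatically."""
    entries: list[FeatureDefinition] = []

    # --- time spans (23): onset-anchored, peak-anchored, and inter-wave spans.
    span_pairs = [
        ("O", "a"), ("O", "w"), ("O", "b"), ("O", "S"), ("O", "c"), ("O", "d"),
        ("O", "N"), ("O", "D"), ("O", "Onext"),
        ("S", "N"), ("S", "D"), ("S", "c-2"), ("S", "d-2"), ("S", "Onext"),
        ("N", "D"),
        ("a", "b"), ("b", "c"), ("b", "d"), ("c", "d"), ("d", "e"),
        ("w", "x"), ("x", "y"), ("y", "z"),
    ]
    entries += [_entry("time_span", _span(f1, f2)) for f1, f2 in span_pairs]

    # --- PPG amplitudes (14): heights above the onset baseline + peak-relative ratios.
    amp_tokens = ["S", "N", "D", "w-1", "a-2", "b-2", "c-2", "d-2", "e-2"]
    entries += [_entry("ppg_amplitude", _amp(t)) for t in amp_tokens]
    for t in ["N", "D", "w-1", "b-2", "c-2"]:
        entries.append(_ratio("ppg_amplitude", _amp(t), _amp("S")))

    # --- VPG/APG values (10).
    for t in ["a", "b", "c", "d", "e", "w", "x", "y", "z", "c-1"]:
        entries.append(_entry("vpg_apg", _val(t)))

    # --- waveform areas (4).
    for f1, f2 in [("O", "S"), ("S", "Onext"), ("O", "c-2"), ("O", "Onext")]:
        entries.append(_entry("waveform_area", _area(f1, f2)))

    # --- power areas (15): five per level.
    pow_pairs = [
        ("O", "S"), ("S", "Onext"), ("O", "Onext"), ("O", "c-2"), ("S", "c-2"),
        ("O+1", "Onext+1"), ("w", "S+1"), ("S+1", "c-1"), ("S+1", "d-1"), ("w", "c-1"),
        ("O+2", "Onext+2"), ("S+2", "c"), ("a", "b"), ("b", "c"), ("b", "d"),
    ]
    entries += [_entry("power_area", _pow(f1, f2)) for f1, f2 in pow_pairs]

    # --- ratios (43).
    ratios: list[FeatureDefinition] = [
        _ratio("ratio", _span("O", "S"), _span("O", "Onext")),
        _ratio("ratio", _area("O", "S"), _area("O", "Onext")),
        _ratio("ratio", _area("O", "c-2"), _area("O", "Onext")),
        _ratio("ratio", _pow("S+1", "c-1"), _pow("O+1", "Onext+1")),
        _ratio("ratio", _pow("S+1", "d-1"), _pow("O+1", "Onext+1")),
        _ratio("ratio", _pow("w", "S+1"), _pow("O+1", "Onext+1")),
        _ratio("ratio", _pow("S+2", "c"), _pow("O+2", "Onext+2"),
               note="truncated-subscript table entry read as the APG-level power ratio"),
        _ratio("ratio", _val("c-1"), _val("w")),
        _ratio("ratio", _val("b"), _val("a")),
        _ratio("ratio", _val("c"), _val("a")),
        _ratio("ratio", _val("d"), _val("a")),
        _ratio("ratio", _val("e"), _val("a")),
        _ratio("ratio", _combo(["b", "c", "d", "e"]), _val("a")),
        _ratio("ratio", _combo(["b", "c", "d"]), _val("a")),
    ]
    for f1, f2 in [("O", "a"), ("O", "w"), ("O", "b"), ("O", "c"), ("O", "d"),
                   ("O", "N"), ("O", "D"), ("S", "N"), ("S", "D"), ("S", "c-2"),
                   ("S", "d-2"), ("b", "c"), ("b", "d"), ("N", "D")]:
        ratios.append(_ratio("ratio", _span(f1, f2), _span("O", "Onext")))
    ratios.append(_ratio("ratio", _area("O", "S"), _area("S", "Onext")))
    for f1, f2 in [("O", "S"), ("S", "Onext"), ("O", "c-2"), ("S", "c-2")]:
        ratios.append(_ratio("ratio", _pow(f1, f2), _pow("O", "Onext")))
    ratios.append(_ratio("ratio", _pow("w", "c-1"), _pow("O+1", "Onext+1")))
    for f1, f2 in [("a", "b"), ("b", "c"), ("b", "d")]:
        ratios.append(_ratio("ratio", _pow(f1, f2), _pow("O+2", "Onext+2")))
    for t in ["x", "y", "z"]:
        ratios.append(_ratio("ratio", _val(t), _val("w")))
    for t in ["a-2", "d-2", "e-2"]:
        ratios.append(_ratio("ratio", _amp(t), _amp("S")))
    entries += ratios

    # --- slopes (16): PPG-level chords.
    slope_pairs = [
        ("O", "S"), ("O", "w-1"), ("O", "a-2"), ("O", "b-2"),
        ("w-1", "S"), ("a-2", "b-2"), ("b-2", "c-2"), ("b-2", "d-2"),
        ("c-2", "d-2"), ("d-2", "e-2"),
        ("S", "N"), ("S", "D"), ("S", "c-2"), ("S", "d-2"), ("S", "Onext"),
        ("N", "D"),
    ]
    entries += [_entry("slope", _slope(f1, f2)) for f1, f2 in slope_pairs]

    _validate(entries)
    return entries


def _iter_tokens(kernel: str, operands: dict):
    if kernel == "ratio":
        for side in ("num", "den"):
            yield from _iter_tokens(operands[side]["kernel"], operands[side]["operands"])
    elif kernel == "apg_combo":
        yield from operands["terms"]
    elif kernel in ("amp", "val"):
        yield operands["token"]
    else:
        yield operands["f1"]
        yield operands["f2"]


def _validate(entries: list[FeatureDefinition]) -> None:
    names = [e.name for e in entries]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate feature names: {dupes}")
    counts: dict[str, int] = {}
    for e in entries:
        counts[e.category] = counts.get(e.category, 0) + 1
        for tok_text in _iter_tokens(e.kernel, e.operands):
            tok = parse_token(tok_text)
            if e.kernel == "amp" and tok.level != 0:
                raise ValueError(f"amplitude token must resolve to PPG level: {e.name}")
            if e.kernel in ("pow", "area", "span", "slope"):
                pass  # level consistency checked at evaluation time
    if counts != CATEGORY_SIZES:
        raise ValueError(f"category counts {counts} != required {CATEGORY_SIZES}")
    if len(entries) != TOTAL_FEATURES:
        raise ValueError(f"catalogue has {len(entries)} entries, expected {TOTAL_FEATURES}")


# ---------------------------------------------------------------------------
# serialisation

def to_json(entries: list[FeatureDefinition]) -> str:
    payload = {
        "version": 1,
        "total": len(entries),
        "features": [
            {"name": e.name, "category": e.category, "kernel": e.kernel,
             "operands": e.operands, **({"note": e.note} if e.note else {})}
            for e in entries
        ],
    }
    return json.dumps(payload, indent=1)


def from_json(text: str) -> list[FeatureDefinition]:
    payload = json.loads(text)
    entries = [
        FeatureDefinition(f["name"], f["category"], f["kernel"], f["operands"],
                          f.get("note", ""))
        for f in payload["features"]
    ]
    _validate(entries)
    return entries


@lru_cache(maxsize=1)
def catalogue() -> tuple[FeatureDefinition, ...]:
    """Load the shipped canonical catalogue (cached)."""
    text = resources.files("ppght").joinpath("data/catalogue.json").read_text()
    return tuple(from_json(text))


def feature_names() -> list[str]:
    return [e.name for e in catalogue()]


def category_counts(entries=None) -> dict[str, int]:
    entries = catalogue() if entries is None else entries
    out: dict[str, int] = {}
    for e in entries:
        out[e.category] = out.get(e.category, 0) + 1
    return out


def lookup(name: str) -> FeatureDefinition:
    """Resolve a canonical feature name to its unique catalogue entry."""
    matches = [e for e in catalogue() if e.name == name]
    if len(matches) != 1:
        raise KeyError(f"feature {name!r} resolves to {len(matches)} catalogue entries")
    return matches[0]
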
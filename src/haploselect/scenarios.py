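"""Preset scenarios, YAML configuration parsing, and result writers.

Presets "A"-"D" are the four published simulation experiments: a shared
baseline rate mu00 = 0.07/yr with additive increments (R1, R2), identical
margins m1 = m2 = 0.4 for A-C but different initial LD (-0.16, 0.23, 0.13),
and an asymmetric fourth row (m1 = 0.28, m2 = 0.41, LD ≈ 0.165).  Haplotype
frequencies are the primary representation; margins/LD are derived views
(the printed LD of row D is rounded while its haplotype frequencies are
exact).  Presets "A2"-"D2" are multiplicative-model analogues with
H1 = 1 + R1 and H2 = 1 + R2 of the matching row — demo specs chosen here,
not published values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .core import (
    AlleleMargins,
    DomainError,
    HaplotypeDistribution,
    HazardSet,
    Model1Spec,
    Model2Spec,
    Scenario,
    ValidationError,
    distribution_from_margins,
    hazards_model1,
    hazards_model2,
)

__all__ = ["RunOptions", "PRESETS", "load_preset", "parse_config", "write_config"]

CONFIG_SCHEMA_VERSION = 1

# (m00, m10, m01, m11), (mu00, R1, R2) per published row
_PRESET_ROWS = {
    "A": ((0.20, 0.40, 0.40, 0.00), (0.07, -0.20, 0.80)),
    "B": ((0.59, 0.01, 0.01, 0.39), (0.07, -0.20, 0.80)),
    "C": ((0.49, 0.11, 0.11, 0.29), (0.07, -0.20, 0.80)),
    "D": ((0.59, 0.00, 0.13, 0.28), (0.07, -0.35, 0.40)),
}


def _build_presets() -> dict[str, Scenario]:
    presets: dict[str, Scenario] = {}
    for name, (freqs, (mu00, r1, r2)) in _PRESET_ROWS.items():
        dist0 = HaplotypeDistribution(*freqs)
        presets[name] = Scenario(
            label=name, dist0=dist0, hazards=hazards_model1(Model1Spec(mu00, r1, r2))
        )
        # multiplicative-model analogue: H1 = 1+R1, H2 = 1+R2 when that obeys
        # H1*H2 > 1; otherwise H2 is rescaled so mu11 matches the additive row
        # (needed for row D, where (1+R1)(1+R2) = 0.91 < 1)
        h1, h2 = 1.0 + r1, 1.0 + r2
        if h1 * h2 <= 1.0:
            h2 = (1.0 + r1 + r2) / h1
        presets[name + "2"] = Scenario(
            label=name + "2",
            dist0=dist0,
            hazards=hazards_model2(Model2Spec(mu00, h1, h2)),
        )
    return presets


PRESETS: dict[str, Scenario] = _build_presets()


def load_preset(name: str) -> Scenario:
    """Return a preset scenario by name ("A"-"D", "A2"-"D2")."""
    try:
        return PRESETS[name]
    except KeyError:
        raise DomainError(
            f"unknown preset {name!r}; available presets: "
            + ", ".join(sorted(PRESETS))
        ) from None


@dataclass(frozen=True)
class RunOptions:
    """Run-time options accompanying a scenario in a config file."""

    locus: int = 1
    step: float = 0.1
    window: tuple[float, float] | None = None
    n: int | None = None
    seed: int | None = None
    censor_age: float | None = None


_TOP_KEYS = {"schema", "label", "t0", "horizon", "dist0", "margins", "model", "options"}
_OPTION_KEYS = {"locus", "step", "window", "n", "seed", "censor_age"}


def _scenario_from_mapping(cfg: dict) -> Scenario:
    extra = set(cfg) - _TOP_KEYS
    if extra:
        raise ValidationError(f"unknown config keys: {sorted(extra)}")
    if cfg.get("schema", CONFIG_SCHEMA_VERSION) != CONFIG_SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported schema version {cfg.get('schema')!r} "
            f"(expected {CONFIG_SCHEMA_VERSION})"
        )
    has_dist = "dist0" in cfg
    has_margins = "margins" in cfg
    if has_dist == has_margins:
        raise ValidationError(
            "exactly one of 'dist0' and 'margins' must be present"
        )
    if has_dist:
        d = cfg["dist0"]
        try:
            dist0 = HaplotypeDistribution(d["m00"], d["m10"], d["m01"], d["m11"])
        except KeyError as e:
            raise ValidationError(f"dist0 missing key {e.args[0]!r}") from None
    else:
        mg = cfg["margins"]
        try:
            dist0 = distribution_from_margins(
                AlleleMargins(mg["m1"], mg["m2"], mg["D"])
            )
        except KeyError as e:
            raise ValidationError(f"margins missing key {e.args[0]!r}") from None

    try:
        model = dict(cfg["model"])
    except KeyError:
        raise ValidationError("config missing key 'model'") from None
    mtype = model.pop("type", None)
    try:
        if mtype == "model1":
            hazards = hazards_model1(Model1Spec(**model))
        elif mtype == "model2":
            hazards = hazards_model2(Model2Spec(**model))
        elif mtype == "explicit":
            hazards = HazardSet(**model)
        else:
            raise ValidationError(
                f"model.type must be 'model1', 'model2' or 'explicit', got {mtype!r}"
            )
    except TypeError as e:
        raise ValidationError(f"model parameters invalid: {e}") from None

    return Scenario(
        label=str(cfg.get("label", "config")),
        dist0=dist0,
        hazards=hazards,
        t0=float(cfg.get("t0", 0.0)),
        horizon=float(cfg.get("horizon", 60.0)),
    )


def parse_config(path) -> tuple[Scenario, RunOptions]:
    """Parse a YAML scenario config; returns (scenario, run options).

    Validation errors name the offending key.  See the package docs for the
    schema; ``schema: 1`` is the current version.
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} is not a mapping")
    scenario = _scenario_from_mapping(cfg)
    opts = dict(cfg.get("options") or {})
    extra = set(opts) - _OPTION_KEYS
    if extra:
        raise ValidationError(f"unknown option keys: {sorted(extra)}")
    window = opts.get("window")
    if window is not None:
        window = (float(window[0]), float(window[1]))
    options = RunOptions(
        locus=int(opts.get("locus", 1)),
        step=float(opts.get("step", 0.1)),
        window=window,
        n=None if opts.get("n") is None else int(opts["n"]),
        seed=None if opts.get("seed") is None else int(opts["seed"]),
        censor_age=None if opts.get("censor_age") is None else float(opts["censor_age"]),
    )
    if options.locus not in (1, 2):
        raise ValidationError(f"options.locus must be 1 or 2, got {options.locus!r}")
    return scenario, options


def write_config(scenario: Scenario, path, options: RunOptions | None = None) -> None:
    """Serialize a scenario (and options) to YAML; inverse of parse_config.

    Hazards are written explicitly — the model parameterization used to build
    them is not retained on the Scenario.
    """
    cfg: dict = {
        "schema": CONFIG_SCHEMA_VERSION,
        "label": scenario.label,
        "t0": scenario.t0,
        "horizon": scenario.horizon,
        "dist0": {
            "m00": scenario.dist0.m00, "m10": scenario.dist0.m10,
            "m01": scenario.dist0.m01, "m11": scenario.dist0.m11,
        },
        "model": {
            "type": "explicit",
            "mu00": scenario.hazards.mu00, "mu10": scenario.hazards.mu10,
            "mu01": scenario.hazards.mu01, "mu11": scenario.hazards.mu11,
        },
    }
    if options is not None:
        opts: dict = {"locus": options.locus, "step": options.step}
        if options.window is not None:
            opts["window"] = list(options.window)
        for key in ("n", "seed", "censor_age"):
            if getattr(options, key) is not None:
                opts[key] = getattr(options, key)
        cfg["options"] = opts
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
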
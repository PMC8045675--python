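"""Run configuration: a single INI file with one flat section per module.

Sections and keys::

    [run]       stages (comma-separated), seed, out_dir, log_level
    [network]   the activator-inhibitor parameters (keys = NetworkParams fields)
    [domain]    rows, cols, h, guide_fraction
    [pattern]   genotype, t_end, noise_amplitude, level_threshold, cv_uniform
    [generate]  preset (fig5c|null), n_per_group, alpha, depth_sigma,
                n_background, panel_seed
    [de]        lfc_threshold, padj_threshold, shrinkage_weight

Unknown sections or keys are rejected by name, and a parsed configuration
serializes back to an equivalent file (parse -> serialize -> parse is the
identity), so runs can always be reproduced from the copy written next to
their outputs.
"""

from __future__ import annotations

import configparser
import io
from dataclasses import dataclass, field, fields, replace

from .petal_pattern import default_params
from .rd_core import NetworkParams

__all__ = [
    "DomainConfig",
    "PatternConfig",
    "GenerateConfig",
    "DEConfig",
    "RunConfig",
]


@dataclass(frozen=True)
class DomainConfig:
    rows: int = 96
    cols: int = 64
    h: float = 1.0
    guide_fraction: float = 1 / 3


@dataclass(frozen=True)
class PatternConfig:
    genotype: str = "F1"
    t_end: float = 150.0
    noise_amplitude: float = 0.01
    level_threshold: float = 0.5
    cv_uniform: float = 0.05


@dataclass(frozen=True)
class GenerateConfig:
    preset: str = "fig5c"
    n_per_group: int = 3
    alpha: float = 0.05
    depth_sigma: float = 0.1
    n_background: int = 2000
    panel_seed: int = 0


@dataclass(frozen=True)
class DEConfig:
    lfc_threshold: float = 1.0
    padj_threshold: float = 0.05
    shrinkage_weight: float = 0.3


_SUBCONFIGS = {
    "domain": DomainConfig,
    "pattern": PatternConfig,
    "generate": GenerateConfig,
    "de": DEConfig,
}


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, round-trippable through one INI file."""

    stages: tuple = ("generate-counts", "run-de", "summaries", "compare")
    seed: int = 0
    out_dir: str = "mbwsim_run"
    log_level: str = "INFO"
    network: NetworkParams = field(default_factory=default_params)
    domain: DomainConfig = field(default_factory=DomainConfig)
    pattern: PatternConfig = field(default_factory=PatternConfig)
    generate: GenerateConfig = field(default_factory=GenerateConfig)
    de: DEConfig = field(default_factory=DEConfig)

    def with_(self, **updates) -> "RunConfig":
        return replace(self, **updates)

    # -- serialization -------------------------------------------------

    def to_ini(self) -> str:
        cp = configparser.ConfigParser()
        cp.optionxform = str  # D_a / D_i are case-sensitive
        cp["run"] = {
            "stages": ", ".join(self.stages),
            "seed": str(self.seed),
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }
        cp["network"] = {k: repr(v) for k, v in self.network.to_dict().items()}
        for name, sub in (("domain", self.domain), ("pattern", self.pattern),
                          ("generate", self.generate), ("de", self.de)):
            cp[name] = {f.name: repr(getattr(sub, f.name)).strip("'")
                        for f in fields(sub)}
        buf = io.StringIO()
        cp.write(buf)
        return buf.getvalue()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_ini())

    @classmethod
    def from_ini(cls, text: str) -> "RunConfig":
        cp = configparser.ConfigParser()
        cp.optionxform = str
        cp.read_string(text)
        known_sections = {"run", "network", *_SUBCONFIGS}
        unknown = set(cp.sections()) - known_sections
        if unknown:
            raise KeyError(f"unknown config section(s): {sorted(unknown)}")

        kwargs: dict = {}
        if cp.has_section("run"):
            run_keys = {"stages", "seed", "out_dir", "log_level"}
            bad = set(cp["run"]) - run_keys
            if bad:
                raise KeyError(f"unknown key(s) in [run]: {sorted(bad)}")
            sec = cp["run"]
            if "stages" in sec:
                kwargs["stages"] = tuple(
                    s.strip() for s in sec["stages"].split(",") if s.strip()
                )
            if "seed" in sec:
                kwargs["seed"] = int(sec["seed"])
            if "out_dir" in sec:
                kwargs["out_dir"] = sec["out_dir"]
            if "log_level" in sec:
                kwargs["log_level"] = sec["log_level"]
        if cp.has_section("network"):
            base = default_params().to_dict()
            base.update({k: float(v) for k, v in cp["network"].items()})
            kwargs["network"] = NetworkParams.from_dict(base)  # rejects unknown keys
        for name, subcls in _SUBCONFIGS.items():
            if not cp.has_section(name):
                continue
            sub_fields = {f.name: f.type for f in fields(subcls)}
            bad = set(cp[name]) - set(sub_fields)
            if bad:
                raise KeyError(f"unknown key(s) in [{name}]: {sorted(bad)}")
            parsed = {}
            defaults = subcls()
            for key, raw in cp[name].items():
                current = getattr(defaults, key)
                parsed[key] = type(current)(raw) if not isinstance(current, str) else raw
            kwargs[name] = replace(defaults, **parsed)
        return cls(**kwargs)

    @classmethod
    def read(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_ini(fh.read())
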
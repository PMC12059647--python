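"""Named parameter presets and flat key-value run configuration.

Two published parameter grids ship as presets.  The first ("table1") is the
comparison grid against earlier large-scale simulations: N0 = 10^6,
u = 3e-8, kappa = 3, L in {1e3..1e6} and scaled selection gamma0 in
{0.02, 2, 200} (the source simulations' selection coefficient is twice this
model's s, so presets are parameterized by gamma0 directly).  The second
("table2") is the native simulation grid: N = 1000, u = 1e-5, kappa = 1,
L in {2500, 10000, 40000}, s in {1e-3, 1e-2}, 200,000 generations,
200 replicates, sample size 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

from .params import ModelParams

#: no-interference neutral diversity of the native simulation grid
TABLE2_N0 = 1000.0
TABLE2_U = 1e-5


def table1_preset(L: float, gamma0: float) -> ModelParams:
    return ModelParams.from_gamma0(N0=1e6, gamma0=gamma0, u=3e-8, kappa=3.0, L=int(L))


def table2_preset(L: int, s: float) -> ModelParams:
    return ModelParams(N0=TABLE2_N0, s=s, u=TABLE2_U, kappa=1.0, L=L)


def _build_registry() -> Dict[str, ModelParams]:
    reg: Dict[str, ModelParams] = {}
    for L in (1e3, 1e4, 1e5, 1e6):
        for g0 in (0.02, 2.0, 200.0):
            reg[f"table1_L{int(L):d}_g{g0:g}"] = table1_preset(L, g0)
    for L in (2500, 10000, 40000):
        for s in (1e-3, 1e-2):
            reg[f"table2_L{L}_s{s:g}"] = table2_preset(L, s)
    reg["table2_neutral"] = ModelParams(
        N0=TABLE2_N0, s=0.0, u=TABLE2_U, kappa=1.0, L=2500
    )
    return reg


PRESETS: Dict[str, ModelParams] = _build_registry()

#: execution defaults of the native simulation study
TABLE2_GENERATIONS = 200_000
TABLE2_REPLICATES = 200
TABLE2_SAMPLE_SIZE = 20


def table1_grid() -> Iterator[Tuple[str, ModelParams]]:
    for name, p in PRESETS.items():
        if name.startswith("table1"):
            yield name, p


def table2_grid(include_neutral: bool = False) -> Iterator[Tuple[str, ModelParams]]:
    for name, p in PRESETS.items():
        if name.startswith("table2") and (include_neutral or p.s > 0):
            yield name, p


@dataclass
class RunConfig:
    """Fully resolved run configuration.

    Built either from explicit parameters or a preset name plus overrides;
    unknown keys are rejected.  Serializes to a flat ``key = value`` text
    block that parses back to an identical config.
    """

    params: ModelParams
    preset: str = ""
    generations: int = TABLE2_GENERATIONS
    replicates: int = 1
    k: int = TABLE2_SAMPLE_SIZE
    n_steps: int = 10
    seed: int = 1
    N: int = 0  # census size for simulation; defaults to round(N0)
    extra: dict = field(default_factory=dict)

    _KEYS = {
        "preset", "N0", "s", "u", "kappa", "L",
        "generations", "replicates", "k", "n_steps", "seed", "N",
    }

    def __post_init__(self) -> None:
        if self.N == 0:
            self.N = int(round(self.params.N0))

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        unknown = set(mapping) - cls._KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        m = dict(mapping)
        preset = m.pop("preset", "")
        if preset:
            base = PRESETS[preset]
            params = ModelParams(
                N0=float(m.pop("N0", base.N0)),
                s=float(m.pop("s", base.s)),
                u=float(m.pop("u", base.u)),
                kappa=float(m.pop("kappa", base.kappa)),
                L=int(float(m.pop("L", base.L))),
            )
        else:
            params = ModelParams(
                N0=float(m.pop("N0")),
                s=float(m.pop("s")),
                u=float(m.pop("u")),
                kappa=float(m.pop("kappa")),
                L=int(float(m.pop("L"))),
            )
        kwargs = {k: int(float(v)) for k, v in m.items()}
        return cls(params=params, preset=preset, **kwargs)

    @classmethod
    def parse(cls, text: str) -> "RunConfig":
        """Parse a flat ``key = value`` block ('#' starts a comment)."""
        mapping: dict = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, val = (x.strip() for x in line.split("=", 1))
            mapping[key] = val
        return cls.from_mapping(mapping)

    def serialize(self) -> str:
        p = self.params
        lines = []
        if self.preset:
            lines.append(f"preset = {self.preset}")
        lines += [
            f"N0 = {p.N0!r}",
            f"s = {p.s!r}",
            f"u = {p.u!r}",
            f"kappa = {p.kappa!r}",
            f"L = {p.L}",
            f"generations = {self.generations}",
            f"replicates = {self.replicates}",
            f"k = {self.k}",
            f"n_steps = {self.n_steps}",
            f"seed = {self.seed}",
            f"N = {self.N}",
        ]
        return "\n".join(lines) + "\n"
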
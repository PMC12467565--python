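"""Run configuration and deterministic random-substream derivation.

Every stochastic operation in the package draws its generator from
:func:`substream`, which maps a (seed, label) pair to an independent
:class:`numpy.random.Generator`. Labels are stable strings ("anosim",
"beta_nti", ...), so a whole study run is bit-reproducible from a single
integer seed while operations remain statistically independent of each
other and of their execution order.
"""
from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass

import numpy as np
import yaml

from .exceptions import UsageError

__all__ = ["RunConfig", "substream", "spawn_seed"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return an independent RNG for ``label`` derived from the run seed."""
    tag = zlib.crc32(label.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def spawn_seed(seed: int, label: str) -> int:
    """A derived integer seed in [0, 2^31) for APIs that take plain ints."""
    return int(substream(seed, label).integers(0, 2**31 - 1))


@dataclass
class RunConfig:
    """Parameters shared by the pipeline stages.

    Attributes
    ----------
    seed:
        Master seed; all stochastic stages derive substreams from it.
    n_permutations:
        Permutations for ANOSIM.
    n_nulls:
        Null draws for the assembly null models (tip shuffles / Raup–Crick
        randomizations).
    n_bootstrap:
        Bootstrap resamples for PLS path-model standard errors.
    r_cut, p_cut, min_prevalence:
        Co-occurrence network thresholds: minimum |Spearman rho|, maximum
        BH-adjusted p, and the fraction of samples a taxon must occupy to
        enter the correlation step.
    bnti_cut, rc_cut:
        Assembly classification thresholds on betaNTI and Raup–Crick(Bray).
    va_convention:
        Enzyme vector-angle atan2 argument ordering: "spreadsheet", "math"
        or "both".
    """

    seed: int = 0
    n_permutations: int = 999
    n_nulls: int = 999
    n_bootstrap: int = 499
    r_cut: float = 0.6
    p_cut: float = 0.05
    min_prevalence: float = 1.0 / 3.0
    bnti_cut: float = 2.0
    rc_cut: float = 0.95
    va_convention: str = "spreadsheet"

    def __post_init__(self) -> None:
        for name in ("n_permutations", "n_nulls", "n_bootstrap"):
            if int(getattr(self, name)) < 1:
                raise UsageError(f"{name} must be >= 1")
        if not 0 < self.r_cut <= 1:
            raise UsageError("r_cut must be in (0, 1]")
        if not 0 < self.p_cut <= 1:
            raise UsageError("p_cut must be in (0, 1]")
        if not 0 <= self.min_prevalence <= 1:
            raise UsageError("min_prevalence must be in [0, 1]")
        if self.bnti_cut <= 0:
            raise UsageError("bnti_cut must be positive")
        if not 0 < self.rc_cut < 1:
            raise UsageError("rc_cut must be in (0, 1)")
        if self.va_convention not in ("spreadsheet", "math", "both"):
            raise UsageError("va_convention must be spreadsheet|math|both")

    def rng(self, label: str) -> np.random.Generator:
        return substream(self.seed, label)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise UsageError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
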
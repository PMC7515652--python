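"""Pipeline configuration, stage seeding and logging setup.

Defaults follow the protocol's published operating point: hill height
0.5 kJ/mol, hill width 0.05 (CV units), bias factor 20, production bias
deposition intervals {20, 30, 50} ps, RC lag 2 ps, 5000 training epochs at
learning rate 2e-4 with hidden width 128, switching R0 = 0.3 nm, contact
cutoff 5 A with a 15% display threshold, a 10-dimensional GMM FES and 75%
credible intervals.  Times are in ps and energies in kJ/mol internally.

Per-stage random seeds are derived from the single global seed through a
fixed stage-key registry (``SeedSequence(entropy=(seed, key))``), so adding
a stage never shifts the random stream of another.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PipelineConfig", "stage_seed", "get_logger"]

# fixed registry: appending new stages must not renumber existing ones
_STAGE_KEYS = {
    "toy": 0,
    "unbiased": 1,
    "features": 2,
    "rc_round1": 3,
    "metad": 4,
    "rc_round2": 5,
    "unbind": 6,
    "rates": 7,
    "landscape": 8,
    "contacts": 9,
    "fixtures": 10,
    "committor": 11,
}


def stage_seed(global_seed: int, stage: str, replica: int = 0) -> int:
    """Deterministic per-stage (and per-replica) seed below 2**31."""
    if stage not in _STAGE_KEYS:
        raise KeyError(f"unknown stage '{stage}'")
    ss = np.random.SeedSequence(entropy=(int(global_seed), _STAGE_KEYS[stage], replica))
    return int(ss.generate_state(1)[0] % (2**31 - 1)) + 1


def get_logger(stage: str, level: int = logging.INFO) -> logging.Logger:
    logger = logging.getLogger(f"unbindkit.{stage}")
    if not logger.handlers and not logging.getLogger().handlers:
        h = logging.StreamHandler()
        h.setFormatter(
            logging.Formatter("%(asctime)s [%(name)s] %(levelname)s: %(message)s")
        )
        logger.addHandler(h)
    logger.setLevel(level)
    return logger


@dataclass
class ToyBlock:
    scenario: str = "three-state-2d"
    step: float = 0.002            # ps
    friction: float = 1.0
    unbiased_steps: int = 100_000
    stride: int = 10
    beta: float = 1.0              # mol/kJ


@dataclass
class FeaturesBlock:
    n_bins: int = 50
    max_clusters: int = 20


@dataclass
class RCBlock:
    lag: float = 2.0               # ps
    epochs: int = 5000
    lr: float = 2e-4
    hidden: int = 128


@dataclass
class MetadBlock:
    hill_height: float = 0.5       # kJ/mol
    hill_width: float = 0.05       # CV units
    bias_factor: float = 20.0
    deposition_interval: float = 25.0  # ps (RC-learning run)
    n_steps: int = 200_000
    stride: int = 10


@dataclass
class UnbindBlock:
    n_replicas: int = 15
    deposition_intervals: tuple[float, ...] = (20.0, 30.0, 50.0)
    production_interval: float = 30.0
    max_steps: int = 2_000_000
    stride: int = 10
    threshold: float = 42.5        # unbinding distance threshold


@dataclass
class BayesBlock:
    cauchy_scale: float = 1.0      # units of inverse mean input time
    log_sigma_mean: float = 1.0
    log_sigma_sd: float = 2.0
    credible_mass: float = 0.75
    n_steps: int = 2500
    n_burn: int = 1000
    n_walkers: int = 40


@dataclass
class LandscapeBlock:
    n_dims: int = 10
    assign_dims: int = 3
    k_min: int = 2
    k_max: int = 8
    neb_images: int = 32
    neb_tol: float = 1e-4


@dataclass
class ContactsBlock:
    R0: float = 0.3                # nm, switching function
    cutoff: float = 5.0            # Angstrom
    display_threshold: float = 0.15


_BLOCKS = {
    "toy": ToyBlock,
    "features": FeaturesBlock,
    "rc": RCBlock,
    "metad": MetadBlock,
    "unbind": UnbindBlock,
    "bayes": BayesBlock,
    "landscape": LandscapeBlock,
    "contacts": ContactsBlock,
}


@dataclass
class PipelineConfig:
    """Stage-by-stage parameter blocks plus the single global seed."""

    seed: int = 0
    toy: ToyBlock = field(default_factory=ToyBlock)
    features: FeaturesBlock = field(default_factory=FeaturesBlock)
    rc: RCBlock = field(default_factory=RCBlock)
    metad: MetadBlock = field(default_factory=MetadBlock)
    unbind: UnbindBlock = field(default_factory=UnbindBlock)
    bayes: BayesBlock = field(default_factory=BayesBlock)
    landscape: LandscapeBlock = field(default_factory=LandscapeBlock)
    contacts: ContactsBlock = field(default_factory=ContactsBlock)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict, require_all: bool = False) -> "PipelineConfig":
        d = dict(d)
        seed = d.pop("seed", 0)
        kwargs: dict = {"seed": int(seed)}
        for name, blk_cls in _BLOCKS.items():
            if name not in d:
                if require_all:
                    raise KeyError(f"config missing required block '{name}'")
                continue
            blk = d.pop(name)
            known = {f.name for f in dataclasses.fields(blk_cls)}
            unknown = set(blk) - known
            if unknown:
                raise KeyError(f"unknown keys in block '{name}': {sorted(unknown)}")
            if "deposition_intervals" in blk:
                blk["deposition_intervals"] = tuple(blk["deposition_intervals"])
            kwargs[name] = blk_cls(**blk)
        if d:
            raise KeyError(f"unknown config blocks: {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def from_toml(cls, path: str | Path, require_all: bool = True) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh), require_all=require_all)

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "PipelineConfig":
        """Operating point sized for the built-in toy landscapes.

        The toy wells are O(1) in CV units and O(1) kT deep per length unit,
        so hill widths, deposition intervals and training epochs are chosen
        for that geometry rather than for the receptor-scale defaults.
        """
        return cls(
            seed=seed,
            toy=ToyBlock(unbiased_steps=60_000, stride=5),
            features=FeaturesBlock(n_bins=30, max_clusters=10),
            rc=RCBlock(lag=0.05, epochs=300, lr=2e-3, hidden=16),
            metad=MetadBlock(
                hill_height=0.4, hill_width=0.15, bias_factor=12.0,
                deposition_interval=0.5, n_steps=150_000, stride=5,
            ),
            unbind=UnbindBlock(
                n_replicas=15, deposition_intervals=(1.0, 2.0, 4.0),
                production_interval=2.0, max_steps=1_500_000, stride=5,
                threshold=2.4,
            ),
            bayes=BayesBlock(n_steps=1200, n_burn=400),
            landscape=LandscapeBlock(n_dims=2, assign_dims=2, k_max=5, neb_images=24),
        )
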
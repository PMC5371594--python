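"""Run configuration: one YAML file drives the whole pipeline.

Schema violations are collected and reported together rather than one at a
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluation import EvalOptions, GridSpec
from .phantom import PhantomSpec

MODES = ("binary", "multiclass", "multimodal")


class ConfigError(ValueError):
    """Raised with the full list of schema violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n" + "\n".join(f"  - {e}" for e in errors))


@dataclass
class RunConfig:
    """Validated configuration with paper-style defaults applied
    (k = 10 folds, C = 2^-3..2^5, q step 0.1, top-5 regions)."""

    mode: str = "binary"
    seed: int = 0
    k: int = 10
    n_perm: int = 1000
    top_regions: int = 5
    grid: GridSpec = field(default_factory=GridSpec)
    phantom: PhantomSpec | None = None
    n_per_group: dict[str, int] | None = None
    regions: list[str] | None = None
    modalities: list[str] = field(default_factory=lambda: ["DMFP"])
    atlas_path: str | None = None
    atlas_names_path: str | None = None
    manifest_path: str | None = None
    outdir: str = "mklpet-out"
    mask_frac: float = 0.05
    merge_lr: bool = True

    def eval_options(self) -> EvalOptions:
        return EvalOptions(
            mode=self.mode,
            k=self.k,
            seed=self.seed,
            grid=self.grid,
            top_regions=self.top_regions,
            primary_modality=self.modalities[0],
            mask_frac=self.mask_frac,
            merge_lr=self.merge_lr,
        )

    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "seed": self.seed,
            "k": self.k,
            "n_perm": self.n_perm,
            "top_regions": self.top_regions,
            "grid": {
                "c_exponents": list(self.grid.c_exponents),
                "q_step": self.grid.q_step,
                "inner_folds": self.grid.inner_folds,
            },
            "modalities": list(self.modalities),
            "outdir": self.outdir,
            "mask_frac": self.mask_frac,
            "merge_lr": self.merge_lr,
        }
        if self.phantom is not None:
            d["phantom"] = self.phantom.to_dict()
        if self.n_per_group is not None:
            d["n_per_group"] = dict(self.n_per_group)
        if self.regions is not None:
            d["regions"] = list(self.regions)
        for key in ("atlas_path", "atlas_names_path", "manifest_path"):
            if getattr(self, key) is not None:
                d[key] = getattr(self, key)
        return d


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML config, applying defaults.

    All schema violations are listed in a single :class:`ConfigError`.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping"])
    errors: list[str] = []

    def take(key, default, types, check=None):
        val = raw.pop(key, default)
        if val is not None and not isinstance(val, types):
            errors.append(f"{key}: expected {types}, got {type(val).__name__}")
            return default
        if check is not None and val is not None:
            msg = check(val)
            if msg:
                errors.append(f"{key}: {msg}")
                return default
        return val

    mode = take("mode", "binary", str, lambda v: None if v in MODES else f"must be one of {MODES}")
    seed = take("seed", 0, int)
    k = take("k", 10, int, lambda v: None if v >= 2 else "must be >= 2")
    n_perm = take("n_perm", 1000, int, lambda v: None if v >= 1 else "must be >= 1")
    top_regions = take("top_regions", 5, int, lambda v: None if v >= 1 else "must be >= 1")
    mask_frac = take(
        "mask_frac", 0.05, (int, float), lambda v: None if 0 < v < 1 else "must be in (0,1)"
    )
    merge_lr = take("merge_lr", True, bool)
    outdir = take("outdir", "mklpet-out", str)
    modalities = take("modalities", ["DMFP"], list) or ["DMFP"]
    regions = take("regions", None, list)
    n_per_group = take("n_per_group", None, dict)

    grid_raw = take("grid", {}, dict) or {}
    try:
        grid = GridSpec(
            c_exponents=tuple(grid_raw.get("c_exponents", range(-3, 6))),
            q_step=float(grid_raw.get("q_step", 0.1)),
            inner_folds=int(grid_raw.get("inner_folds", 5)),
        )
    except (ValueError, TypeError) as e:
        errors.append(f"grid: {e}")
        grid = GridSpec()

    phantom_raw = take("phantom", None, dict)
    phantom = None
    if phantom_raw is not None:
        try:
            phantom = PhantomSpec.from_dict(phantom_raw)
        except (ValueError, TypeError, KeyError) as e:
            errors.append(f"phantom: {e}")

    paths = {}
    for key in ("atlas_path", "atlas_names_path", "manifest_path"):
        paths[key] = take(key, None, str)

    for leftover in raw:
        errors.append(f"unknown field {leftover!r}")
    if errors:
        raise ConfigError(errors)

    return RunConfig(
        mode=mode,
        seed=seed,
        k=k,
        n_perm=n_perm,
        top_regions=top_regions,
        grid=grid,
        phantom=phantom,
        n_per_group=n_per_group,
        regions=regions,
        modalities=modalities,
        outdir=outdir,
        mask_frac=mask_frac,
        merge_lr=merge_lr,
        **paths,
    )


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
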
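"""Dominant-parameter screening from canonical loadings.

A parameter is "remarkable" for a CCA group when the absolute value of its
canonical loading reaches a threshold (default 0.3, inclusive: a bar that
touches the line counts) on at least one retained canonical pair.  A
simplified feature combination for a block is derived across one or more
stage-wise CCA groups by dropping parameters that fail the remarkability
test under the configured rule:

* ``weak_in_all_groups`` — dropped only when weak in *every* listed group
  (used when groups are alternative views of the same stages);
* ``weak_in_any_group`` — dropped when weak in *at least one* listed group
  (used when the listed groups jointly cover the whole experiment period
  and sustained influence is required).

Growth-side (Y) screening can be computed and reported, but combinations
are derived for the X side only; growth targets are never dropped.

Four named presets reproduce the simplified combinations of the reference
trial: ``E_6D`` (environment without e3/CO2 and e5/AH), ``P_8D_6_9``
(physiology without p6/PhiCO2 and p9/Tr, for mid-stage growth), ``P_9D_9``
(without p9, for final growth) and ``P_8D_9_10`` (without p9 and p10/VpdL,
for final growth from any stage's physiology).  ``E_8D`` and ``P_10D`` are
the unsimplified full blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

from .blocks import ENV_PARAMS, PHYSIO_PARAMS
from .cca import CCAResult

__all__ = [
    "ScreeningConfig",
    "FeatureCombination",
    "remarkable_parameters",
    "derive_combination",
    "derive_preset",
    "full_combination",
    "COMBINATION_PRESETS",
    "FULL_COMBINATIONS",
]

DROP_RULES = ("weak_in_all_groups", "weak_in_any_group")


@dataclass(frozen=True)
class ScreeningConfig:
    """Threshold, group list and drop rule for one combination decision."""

    loading_threshold: float = 0.3
    groups: tuple[tuple[str, str], ...] = ()
    drop_rule: str = "weak_in_all_groups"

    def __post_init__(self) -> None:
        if not 0.0 < self.loading_threshold < 1.0:
            raise ValueError("loading_threshold must lie in (0, 1)")
        if self.drop_rule not in DROP_RULES:
            raise ValueError(f"drop_rule must be one of {DROP_RULES}")
        object.__setattr__(self, "groups", tuple(tuple(g) for g in self.groups))


@dataclass(frozen=True)
class FeatureCombination:
    """A named ordered subset of one block's parameters."""

    name: str
    parameter_ids: tuple[str, ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        ids = tuple(self.parameter_ids)
        if not ids:
            raise ValueError(f"combination {self.name!r} is empty")
        if len(set(ids)) != len(ids):
            raise ValueError(f"combination {self.name!r} has duplicate ids")
        object.__setattr__(self, "parameter_ids", ids)

    def __len__(self) -> int:
        return len(self.parameter_ids)


def remarkable_parameters(
    result: CCAResult,
    side: str = "x",
    config: ScreeningConfig | None = None,
) -> tuple[str, ...]:
    """Parameters whose |loading| reaches the threshold on a retained pair."""
    cfg = config or ScreeningConfig()
    if side not in ("x", "y"):
        raise ValueError("side must be 'x' or 'y'")
    loadings = result.cl_xu if side == "x" else result.cl_yv
    params = result.x_params if side == "x" else result.y_params
    if not result.concerned_pairs:
        warnings.warn(
            f"({result.x_name},{result.y_name}): no retained canonical pairs; "
            "no parameter can be judged remarkable",
            stacklevel=2,
        )
        return ()
    cols = [i - 1 for i in result.concerned_pairs]
    return tuple(
        pid for j, pid in enumerate(params)
        if max(abs(loadings[j, c]) for c in cols) >= cfg.loading_threshold
    )


def derive_combination(
    results_by_group: Mapping[tuple[str, str], CCAResult],
    side: str = "x",
    config: ScreeningConfig | None = None,
    name: str = "combination",
) -> FeatureCombination:
    """Drop parameters that fail the remarkability rule across groups.

    All listed groups must analyse the same source block (same parameter
    ids on the chosen side); surviving parameters keep their block order.
    """
    cfg = config or ScreeningConfig()
    groups = cfg.groups or tuple(results_by_group)
    missing = [g for g in groups if g not in results_by_group]
    if missing:
        raise KeyError(f"no CCA result for group(s) {missing}")
    results = [results_by_group[g] for g in groups]
    param_sets = {
        (r.x_params if side == "x" else r.y_params) for r in results
    }
    if len(param_sets) != 1:
        raise ValueError(
            f"groups {list(groups)} do not share a common {side}-side block"
        )
    params = param_sets.pop()
    verdicts = {
        g: set(remarkable_parameters(r, side, cfg))
        for g, r in zip(groups, results)
    }
    if cfg.drop_rule == "weak_in_all_groups":
        keep = [p for p in params if any(p in v for v in verdicts.values())]
    else:  # weak_in_any_group: sustained influence required
        keep = [p for p in params if all(p in v for v in verdicts.values())]
    return FeatureCombination(
        name=name,
        parameter_ids=tuple(keep),
        provenance={
            "groups": [list(g) for g in groups],
            "drop_rule": cfg.drop_rule,
            "loading_threshold": cfg.loading_threshold,
            "dropped": [p for p in params if p not in keep],
        },
    )


# --------------------------------------------------------------------------
# Named presets: which CCA groups feed which combination, and under which
# rule.  The group assignments follow the stage reasoning of the reference
# trial (e.g. E_6D judges environmental influence on mid- and late-stage
# growth; P_8D_9_10 requires influence on final growth sustained across all
# three physiological sampling stages).
# --------------------------------------------------------------------------

COMBINATION_PRESETS: dict[str, ScreeningConfig] = {
    "E_6D": ScreeningConfig(groups=(("E", "G2"), ("E", "G3"))),
    "P_8D_6_9": ScreeningConfig(groups=(("P3", "G2"),)),
    "P_9D_9": ScreeningConfig(groups=(("P4", "G3"),)),
    "P_8D_9_10": ScreeningConfig(
        groups=(("P1", "G3"), ("P2", "G3"), ("P3", "G3")),
        drop_rule="weak_in_any_group",
    ),
}

FULL_COMBINATIONS: dict[str, FeatureCombination] = {
    "E_8D": FeatureCombination("E_8D", ENV_PARAMS, {"preset": "full block"}),
    "P_10D": FeatureCombination("P_10D", PHYSIO_PARAMS, {"preset": "full block"}),
}


def full_combination(name: str) -> FeatureCombination:
    return FULL_COMBINATIONS[name]


def derive_preset(
    name: str,
    results_by_group: Mapping[tuple[str, str], CCAResult],
    loading_threshold: float = 0.3,
) -> FeatureCombination:
    """Derive one of the named simplified combinations from CCA results."""
    base = COMBINATION_PRESETS[name]
    cfg = ScreeningConfig(
        loading_threshold=loading_threshold,
        groups=base.groups,
        drop_rule=base.drop_rule,
    )
    return derive_combination(results_by_group, side="x", config=cfg, name=name)
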
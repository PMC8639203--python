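"""Synthetic cohort generator for chronic vestibular syndromes.

Emulates the marginal structure of the reference study's cohort: four
diagnostic groups (PPPD, CDA, UVH, UD) plus an excluded "other"
stratum, per-group x per-item means/SDs with instrument-range clipping
and type-appropriate rounding, per-item missingness counts, a vHIT
sub-cohort (56 PPPD / 6 UVH) with Bernoulli catch-up-saccade rates, and
caloric CP% values that arise from an actual four-irrigation response
quadruple via the Jongkees formula.

Items are drawn independently within a patient (the study reports only
marginal moments); questionnaire totals are computed by summation from
their subscales, never drawn. All randomness flows from a single seed
through named sub-streams, so each stage is independently reproducible.
"""
from __future__ import annotations

import json
from importlib import resources
from typing import Literal, Mapping, Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .instruments import CaloricRaw, jongkees_cp

__all__ = [
    "GroupParams",
    "ItemStats",
    "ItemSpec",
    "load_default_params",
    "load_params",
    "generate_cohort",
    "sample_item",
    "generate_caloric_raw",
    "inject_missingness",
    "generate_vhit_subcohort",
    "complete_case_mask",
    "REQUIRED_ITEMS",
    "COHORT_COLUMNS",
]

DISEASES = ("PPPD", "CDA", "UVH", "UD")

#: items a record must have for the sequential algorithms (vHIT catch-up
#: saccades are deliberately not required: the vHIT was performed only in
#: a sub-cohort, and a missing CUS observation counts as a negative
#: criterion rather than excluding the patient).
REQUIRED_ITEMS = ("NPQ_visual", "NPQ_total", "HADS_anxiety", "age", "CP_percent")

COHORT_COLUMNS = [
    "id", "true_diagnosis", "age",
    "HADS_anxiety", "HADS_depression", "HADS_total",
    "DHI_physical", "DHI_emotional", "DHI_functional", "DHI_total",
    "NPQ_upright", "NPQ_movement", "NPQ_visual", "NPQ_total",
    "CP_percent", "DP_percent", "cvemp_iaar", "ovemp_iaar",
    "foam_ratio", "romberg_ratio_foam", "vor_dp_percent",
    "vhit_gain_better", "vhit_gain_worse", "vhit_ar", "cus_present",
]


class ItemStats(BaseModel):
    """Mean/SD and available-case count for one group x item cell."""

    mean: float
    sd: float = Field(ge=0)
    n: int = Field(ge=0)


class ItemSpec(BaseModel):
    kind: Literal["integer", "even_integer", "continuous"]
    range: tuple[float, float]
    block: str
    groups: dict[str, ItemStats]

    @model_validator(mode="after")
    def _range_ordered(self) -> "ItemSpec":
        if self.range[0] >= self.range[1]:
            raise ValueError(f"empty range {self.range}")
        return self


class TotalSpec(BaseModel):
    components: list[str]
    targets: dict[str, ItemStats]


class GainStats(BaseModel):
    mean: float
    sd: float = Field(ge=0)


class VhitParams(BaseModel):
    subcohort_sizes: dict[str, int]
    gain_range: tuple[float, float]
    gain_better: dict[str, GainStats]
    gain_worse: dict[str, GainStats]
    cus_rate: dict[str, float]
    low_gain_rate: dict[str, float]
    low_gain_threshold: float = 0.6

    @model_validator(mode="after")
    def _rates_valid(self) -> "VhitParams":
        for rates in (self.cus_rate, self.low_gain_rate):
            for g, r in rates.items():
                if not 0 <= r <= 1:
                    raise ValueError(f"rate for {g} outside [0, 1]: {r}")
        return self


class CaloricTotal(BaseModel):
    mean: float
    sd: float = Field(ge=0)
    range: tuple[float, float]


class OtherStratum(BaseModel):
    age_mean: float
    age_sd: float = Field(ge=0)
    age_range: tuple[float, float]


class GroupParams(BaseModel):
    """Distribution parameters for the full synthetic cohort."""

    model_config = ConfigDict(frozen=True)

    group_sizes: dict[str, int]
    items: dict[str, ItemSpec]
    derived_totals: dict[str, TotalSpec]
    vhit: VhitParams
    caloric_total: CaloricTotal
    other_stratum: OtherStratum

    @model_validator(mode="after")
    def _consistent(self) -> "GroupParams":
        for name, spec in self.items.items():
            for g, st in spec.groups.items():
                size = self.group_sizes.get(g)
                if size is None:
                    raise ValueError(f"item {name}: unknown group {g}")
                if st.n > size:
                    raise ValueError(f"item {name}, group {g}: n={st.n} > group size {size}")
        for g, k in self.vhit.subcohort_sizes.items():
            if k > self.group_sizes.get(g, 0):
                raise ValueError(f"vHIT sub-cohort for {g} larger than group")
        return self


def load_params(path) -> GroupParams:
    """Load :class:`GroupParams` from a JSON or YAML file."""
    text = open(path, "r", encoding="utf-8").read()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return GroupParams.model_validate(data)


def load_default_params() -> GroupParams:
    """Parameters pre-filled with the reference study's group statistics."""
    text = resources.files("vestibattery.data").joinpath("group_params.json").read_text()
    return GroupParams.model_validate(json.loads(text))


def _round_kind(values: np.ndarray, kind: str) -> np.ndarray:
    if kind == "integer":
        return np.rint(values)
    if kind == "even_integer":
        return 2.0 * np.rint(values / 2.0)
    return values


def _draw_clipped(
    mean: float, sd: float, lo: float, hi: float, kind: str, rng: np.random.Generator, size: int
) -> np.ndarray:
    vals = rng.normal(mean, sd, size=size)
    vals = np.clip(vals, lo, hi)
    return np.clip(_round_kind(vals, kind), lo, hi)


def sample_item(
    params: GroupParams,
    diagnosis: str,
    item: str,
    rng: np.random.Generator,
    size: Optional[int] = None,
) -> Union[float, np.ndarray]:
    """Draw value(s) for one item in one group: clipped normal, then
    rounded according to the item's class (integer questionnaire scores,
    even-integer DHI items, continuous ratios)."""
    spec = params.items.get(item)
    if spec is None or diagnosis not in spec.groups:
        raise KeyError(f"no parameters for item {item!r} in group {diagnosis!r}")
    st = spec.groups[diagnosis]
    out = _draw_clipped(st.mean, st.sd, spec.range[0], spec.range[1], spec.kind, rng, size or 1)
    return out if size is not None else float(out[0])


def generate_caloric_raw(
    target_cp: float,
    target_total: float,
    weaker_side: str,
    rng: np.random.Generator,
) -> CaloricRaw:
    """Construct a caloric response quadruple with a prescribed canal paresis.

    The stronger/weaker ear sums are ``total * (1 +- cp/100) / 2`` and each
    ear's sum is split between warm and cool irrigation by a random
    proportion, so :func:`~vestibattery.instruments.jongkees_cp` on the
    result recovers ``target_cp`` exactly (up to float round-off).
    """
    if not 0 <= target_cp <= 100:
        raise ValueError(f"target_cp outside [0, 100]: {target_cp}")
    if target_total <= 0:
        raise ValueError(f"target_total must be > 0: {target_total}")
    if weaker_side not in ("left", "right"):
        raise ValueError(f"weaker_side must be 'left' or 'right', got {weaker_side!r}")
    stronger = target_total * (1 + target_cp / 100.0) / 2.0
    weaker = target_total * (1 - target_cp / 100.0) / 2.0
    frac_strong, frac_weak = rng.uniform(0.25, 0.75, size=2)
    if weaker_side == "left":
        right, left = stronger, weaker
        return CaloricRaw(
            right_warm=right * frac_strong, right_cool=right * (1 - frac_strong),
            left_warm=left * frac_weak, left_cool=left * (1 - frac_weak),
        )
    left, right = stronger, weaker
    return CaloricRaw(
        right_warm=right * frac_weak, right_cool=right * (1 - frac_weak),
        left_warm=left * frac_strong, left_cool=left * (1 - frac_strong),
    )


def _scaled(count: int, scale: float) -> int:
    return int(round(count * scale))


def _draw_cp_via_caloric(
    params: GroupParams, group: str, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Draw target CP% values and realize each through a response quadruple."""
    spec = params.items["CP_percent"]
    st = spec.groups[group]
    targets = _draw_clipped(st.mean, st.sd, spec.range[0], spec.range[1], "continuous", rng, size)
    ct = params.caloric_total
    totals = np.clip(rng.normal(ct.mean, ct.sd, size=size), ct.range[0], ct.range[1])
    sides = rng.choice(["left", "right"], size=size)
    out = np.empty(size)
    for i in range(size):
        quad = generate_caloric_raw(float(targets[i]), float(totals[i]), str(sides[i]), rng)
        out[i] = jongkees_cp(quad)[0]
    return out


def inject_missingness(
    cohort: pd.DataFrame,
    params: GroupParams,
    rng_or_seed: Union[int, np.random.Generator],
    scale: float = 1.0,
) -> pd.DataFrame:
    """Blank out values so each group x item cell has exactly its
    available-case count.

    Missingness is applied jointly per test/questionnaire block (a patient
    who lacks the NPQ lacks all three factors), which is also what the
    per-item counts imply: within every block the printed n are equal.
    Totals computed afterwards inherit their components' mask. Returns a
    modified copy; deterministic given the seed/generator state.
    """
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    out = cohort.copy()
    blocks: dict[str, list[str]] = {}
    for name, spec in params.items.items():
        blocks.setdefault(spec.block, []).append(name)
    for block, item_names in sorted(blocks.items()):
        for group in DISEASES:
            ns = {params.items[i].groups[group].n for i in item_names}
            if len(ns) != 1:
                raise ValueError(f"block {block!r} has unequal n across items in {group}")
            rows = np.flatnonzero((out["true_diagnosis"] == group).to_numpy())
            size = len(rows)
            n_avail = min(size, _scaled(ns.pop(), scale))
            n_missing = size - n_avail
            if n_missing <= 0:
                continue
            chosen = rng.choice(rows, size=n_missing, replace=False)
            out.iloc[np.sort(chosen), [out.columns.get_loc(i) for i in item_names]] = np.nan
    return out


def generate_vhit_subcohort(
    cohort: pd.DataFrame, params: GroupParams, rng: np.random.Generator, scale: float = 1.0
) -> pd.DataFrame:
    """Assign vHIT gains, asymmetry ratio and catch-up-saccade status to a
    random PPPD/UVH subset (56 and 6 patients at scale 1).

    Better/worse gains are clipped normal draws ordered within-patient;
    the asymmetry ratio is computed from them; catch-up saccades are
    Bernoulli with the group's observed rate (1/56 PPPD, 3/6 UVH).
    """
    out = cohort.copy()
    v = params.vhit
    lo, hi = v.gain_range
    for group, sub_n in sorted(v.subcohort_sizes.items()):
        rows = np.flatnonzero((out["true_diagnosis"] == group).to_numpy())
        k = min(len(rows), _scaled(sub_n, scale))
        chosen = np.sort(rng.choice(rows, size=k, replace=False))
        a = np.clip(rng.normal(v.gain_better[group].mean, v.gain_better[group].sd, k), lo, hi)
        b = np.clip(rng.normal(v.gain_worse[group].mean, v.gain_worse[group].sd, k), lo, hi)
        better, worse = np.maximum(a, b), np.minimum(a, b)
        ar = np.abs(better - worse) / (better + worse) * 100.0
        cus = rng.random(k) < v.cus_rate[group]
        out.iloc[chosen, out.columns.get_loc("vhit_gain_better")] = better
        out.iloc[chosen, out.columns.get_loc("vhit_gain_worse")] = worse
        out.iloc[chosen, out.columns.get_loc("vhit_ar")] = ar
        col = out.columns.get_loc("cus_present")
        out.iloc[chosen, col] = pd.array(cus, dtype="boolean")
    return out


def generate_cohort(
    params: Optional[GroupParams] = None,
    seed: int = 0,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Generate a labeled synthetic cohort as a DataFrame.

    Parameters
    ----------
    params
        Distribution parameters; defaults to the reference study's values.
    seed
        Master seed; sub-streams for value draws, caloric quadruples, the
        vHIT sub-cohort and the missingness mask are spawned from it, so
        the output is fully deterministic.
    scale
        Multiplies every group size (and per-cell available n), rounded.
        ``scale=1`` reproduces the study's sizes 92/44/31/37 (+27 other).
    """
    params = params or load_default_params()
    if scale <= 0:
        raise ValueError("scale must be positive")
    ss = np.random.SeedSequence(seed)
    s_values, s_caloric, s_vhit, s_missing = ss.spawn(4)
    rng_values = np.random.default_rng(s_values)
    rng_caloric = np.random.default_rng(s_caloric)

    frames = []
    for group in DISEASES:
        size = _scaled(params.group_sizes[group], scale)
        cols: dict[str, np.ndarray] = {}
        for item in params.items:
            if item == "CP_percent":
                continue
            cols[item] = sample_item(params, group, item, rng_values, size=size)
        cols["CP_percent"] = _draw_cp_via_caloric(params, group, rng_caloric, size)
        df = pd.DataFrame(cols)
        df.insert(0, "true_diagnosis", group)
        frames.append(df)

    other_n = _scaled(params.group_sizes.get("OTHER", 0), scale)
    if other_n:
        o = params.other_stratum
        ages = _draw_clipped(
            o.age_mean, o.age_sd, o.age_range[0], o.age_range[1], "integer",
            rng_values, other_n,
        )
        frames.append(pd.DataFrame({"true_diagnosis": "OTHER", "age": ages}))

    cohort = pd.concat(frames, ignore_index=True)
    for col in COHORT_COLUMNS:
        if col not in cohort.columns:
            cohort[col] = np.nan
    cohort["cus_present"] = pd.array([pd.NA] * len(cohort), dtype="boolean")
    cohort["id"] = [f"P{i + 1:04d}" for i in range(len(cohort))]

    cohort = inject_missingness(cohort, params, np.random.default_rng(s_missing), scale)
    for total, spec in params.derived_totals.items():
        cohort[total] = sum(cohort[c] for c in spec.components)
    cohort = generate_vhit_subcohort(cohort, params, np.random.default_rng(s_vhit), scale)
    return cohort[COHORT_COLUMNS]


def complete_case_mask(
    cohort: pd.DataFrame, required: tuple[str, ...] = REQUIRED_ITEMS
) -> pd.Series:
    """Boolean mask of records with every required battery item observed."""
    mask = pd.Series(True, index=cohort.index)
    for item in required:
        mask &= cohort[item].notna()
    return mask
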
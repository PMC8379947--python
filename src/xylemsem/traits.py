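"""Reading, validating, transforming, and deriving the nine analysis traits.

The unit of analysis is the species mean (about six replicate stems per
species); replicate-level tables carry ``site`` and ``replicate`` labels
and can be aggregated on load.  Before model fitting the water
potentials (negative by sign convention) are folded to absolute values
and all traits except xylem density and capacitance are natural-log
transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .xylem_models import TRAIT_NAMES

__all__ = [
    "TraitTable",
    "TransformSpec",
    "TraitDataError",
    "DEFAULT_TRANSFORMS",
    "load_trait_table",
    "apply_transforms",
    "invert_transforms",
    "relative_water_content",
    "capacitance_from_pv_curve",
    "xylem_specific_conductivity",
]


class TraitDataError(ValueError):
    """Invalid trait data: missing columns, bad signs, out-of-range values."""


_PROPORTION_TRAITS = ("fiber", "vessel", "parenchyma")
_NEGATIVE_TRAITS = ("pmin", "p75")


@dataclass
class TraitTable:
    """Species x trait matrix with labels and transform bookkeeping.

    ``data`` holds one row per species (species level) or one row per
    stem (replicate level); ``transforms`` records, per trait column,
    the transform already applied ("identity", "abs_log", ...), so a
    second transformation is refused.
    """

    data: pd.DataFrame
    level: str = "species"
    transforms: dict[str, str] = field(default_factory=dict)

    @property
    def traits(self) -> pd.DataFrame:
        return self.data[list(TRAIT_NAMES)]

    @property
    def species(self) -> list[str]:
        return list(self.data["species"])

    def covariance(self, ddof: int = 1) -> pd.DataFrame:
        x = self.traits.to_numpy(dtype=float)
        c = np.cov(x, rowvar=False, ddof=ddof)
        return pd.DataFrame(c, index=TRAIT_NAMES, columns=TRAIT_NAMES)


@dataclass(frozen=True)
class TransformSpec:
    """Per-trait transform rules: natural log or identity, with an
    absolute-value rule for the (negative) water potentials.

    The absolute value is taken first, then the log — forced by the
    domain of the logarithm.  An optional per-trait scaling constant
    (division) may be supplied; scaling is off by default and recorded
    in the table's transform metadata when used.
    """

    log_traits: tuple[str, ...] = (
        "pmin", "p75", "ks", "starch", "fiber", "vessel", "parenchyma",
    )
    abs_traits: tuple[str, ...] = ("pmin", "p75")
    scale: dict[str, float] | None = None

    def rule(self, trait: str) -> str:
        parts = []
        if trait in self.abs_traits:
            parts.append("abs")
        if trait in self.log_traits:
            parts.append("log")
        if self.scale and trait in self.scale:
            parts.append(f"scale/{self.scale[trait]:g}")
        return "_".join(parts) if parts else "identity"


DEFAULT_TRANSFORMS = TransformSpec()
# the two identity traits are exactly xylem density and capacitance
assert set(TRAIT_NAMES) - set(DEFAULT_TRANSFORMS.log_traits) == {
    "density", "capacitance",
}


def load_trait_table(
    path, level: str = "species", aggregate: bool = True,
    transformed: bool = False,
) -> TraitTable:
    """Read a trait CSV and validate it.

    Required columns: ``species``, the nine trait names, plus ``site``
    (and optionally ``replicate``) for replicate-level tables.  A
    replicate-level file is aggregated to species means (arithmetic
    mean over available replicates) when ``level="species"`` and
    ``aggregate`` is true.  ``transformed=True`` declares the file to be
    on the analysis (post-transform) scale: raw-scale sign and range
    checks are skipped and the table is marked so a second transform is
    refused.
    """
    df = pd.read_csv(path)
    return _validate_table(df, level=level, aggregate=aggregate,
                           transformed=transformed)


def _validate_table(df: pd.DataFrame, level: str, aggregate: bool = True,
                    transformed: bool = False) -> TraitTable:
    if level not in ("species", "replicate"):
        raise TraitDataError(f"unknown level {level!r}")
    missing = [c for c in ("species", *TRAIT_NAMES) if c not in df.columns]
    if missing:
        raise TraitDataError(f"missing required column(s): {missing}")
    for col in TRAIT_NAMES:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().sum() > df[col].isna().sum():
            raise TraitDataError(f"non-numeric cell in column {col!r}")
        df = df.assign(**{col: vals})
    if not transformed:
        for col in _PROPORTION_TRAITS:
            v = df[col].dropna()
            if ((v < 0) | (v > 1)).any():
                raise TraitDataError(
                    f"proportion outside [0, 1] in column {col!r}")
        for col in _NEGATIVE_TRAITS:
            if (df[col].dropna() > 0).any():
                raise TraitDataError(
                    f"positive water potential in column {col!r}; "
                    "water potentials must be <= 0 before transforms"
                )

    is_replicate_file = "replicate" in df.columns or df["species"].duplicated().any()
    if level == "species" and is_replicate_file and aggregate:
        keys = ["species"] + (["site"] if "site" in df.columns else [])
        agg = df.groupby(keys, sort=True, as_index=False)[list(TRAIT_NAMES)].mean()
        df = agg
        level_out = "species"
    else:
        level_out = level

    if level_out == "species":
        if df["species"].duplicated().any():
            dups = df.loc[df["species"].duplicated(), "species"].tolist()
            raise TraitDataError(f"duplicate species rows: {dups}")
        if df[list(TRAIT_NAMES)].isna().any().any():
            bad = df.loc[df[list(TRAIT_NAMES)].isna().any(axis=1), "species"].tolist()
            raise TraitDataError(
                f"species with missing trait cells after aggregation: {bad}; "
                "the covariance-structure model requires complete data"
            )
    marks = ({c: DEFAULT_TRANSFORMS.rule(c) for c in TRAIT_NAMES}
             if transformed else {})
    return TraitTable(data=df.reset_index(drop=True), level=level_out,
                      transforms=marks)


def apply_transforms(
    table: TraitTable, spec: TransformSpec = DEFAULT_TRANSFORMS
) -> TraitTable:
    """Apply the per-trait transform rules, returning a new table.

    Refuses to transform twice, and refuses the log of a non-positive
    value (after the absolute-value rule).
    """
    for col in TRAIT_NAMES:
        if table.transforms.get(col, "raw") != "raw" and spec.rule(col) != "identity":
            raise TraitDataError(f"column {col!r} already transformed")
    df = table.data.copy()
    applied: dict[str, str] = {}
    for col in TRAIT_NAMES:
        x = df[col].to_numpy(dtype=float)
        if col in spec.abs_traits:
            x = np.abs(x)
        if col in spec.log_traits:
            if np.any(x <= 0):
                raise TraitDataError(
                    f"log transform of non-positive value in column {col!r}"
                )
            x = np.log(x)
        if spec.scale and col in spec.scale:
            x = x / spec.scale[col]
        df[col] = x
        applied[col] = spec.rule(col)
    return TraitTable(data=df, level=table.level, transforms=applied)


def invert_transforms(
    table: TraitTable, spec: TransformSpec = DEFAULT_TRANSFORMS
) -> TraitTable:
    """Undo :func:`apply_transforms` (signs of the water potentials are
    restored to negative)."""
    df = table.data.copy()
    for col in TRAIT_NAMES:
        x = df[col].to_numpy(dtype=float)
        if spec.scale and col in spec.scale:
            x = x * spec.scale[col]
        if col in spec.log_traits:
            x = np.exp(x)
        if col in spec.abs_traits:
            x = -x
        df[col] = x
    return TraitTable(data=df, level=table.level, transforms={})


def relative_water_content(fresh: float, dry: float, saturated: float) -> float:
    """RWC = (fresh - dry) / (saturated - dry), a fraction in [0, 1].

    Warns (does not error) above 1, which can occur from weighing noise
    near full saturation.
    """
    if saturated <= dry:
        raise TraitDataError("saturated weight must exceed dry weight")
    if fresh < dry:
        raise TraitDataError("fresh weight below dry weight")
    rwc = (fresh - dry) / (saturated - dry)
    if rwc > 1:
        warnings.warn(f"relative water content {rwc:.4f} exceeds 1")
    return rwc


def capacitance_from_pv_curve(
    points, window: tuple[float, float] = (-1.5, -0.3)
) -> float:
    """Capacitance from a pressure-volume curve: the OLS slope of RWC on
    water potential over the near-linear window (default -1.5 to -0.3 MPa).

    Returned as a positive magnitude (RWC per MPa).  The raw OLS slope
    against increasingly negative potential is positive in the usual
    orientation (RWC falls as potential falls); the magnitude convention
    makes the stored trait sign-free.
    """
    pts = [(float(p), float(r)) for p, r in points]
    lo, hi = min(window), max(window)
    inside = [(p, r) for p, r in pts if lo <= p <= hi]
    if len(inside) < 2:
        raise TraitDataError(
            f"need >=2 pressure-volume points inside [{lo}, {hi}] MPa, "
            f"got {len(inside)}"
        )
    psi = np.array([p for p, _ in inside])
    rwc = np.array([r for _, r in inside])
    slope = np.polyfit(psi, rwc, 1)[0]
    return float(abs(slope))


def xylem_specific_conductivity(
    flow: float, gradient: float, sapwood_area: float
) -> float:
    """K_s = (flow rate / pressure gradient) / sapwood area.

    flow in kg/s, gradient in MPa/m, area in m^2; K_s in
    kg s^-1 m^-1 MPa^-1.
    """
    if gradient <= 0:
        raise TraitDataError("pressure gradient must be positive")
    if sapwood_area <= 0:
        raise TraitDataError("sapwood area must be positive")
    if flow < 0:
        raise TraitDataError("flow rate must be non-negative")
    return (flow / gradient) / sapwood_area
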
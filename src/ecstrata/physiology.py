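"""Gut-transit readouts and qPCR relative expression.

Deterministic formulas: gastric emptying rate from recovered fluorescence,
the geometric center of small-intestinal transit over 10 equal segments,
colonic dye travel as a fraction of colon length, and ΔΔCt fold-changes
against an aggregate of housekeeping genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

N_SI_SEGMENTS = 10
DEFAULT_HOUSEKEEPING = ("B2m", "Gapdh", "Rpl13a")


@dataclass
class TransitProfile:
    """Per-animal fluorescence recovered from stomach, 10 small-intestine
    segments (proximal → distal) and colon."""

    stomach: float
    si_segments: np.ndarray
    colon: float

    def __post_init__(self) -> None:
        self.si_segments = np.asarray(self.si_segments, dtype=float)
        if self.si_segments.shape != (N_SI_SEGMENTS,):
            raise ValidationError(
                f"expected exactly {N_SI_SEGMENTS} small-intestine segments, "
                f"got {self.si_segments.shape}"
            )
        if (
            self.stomach < 0
            or self.colon < 0
            or np.any(self.si_segments < 0)
            or not np.all(np.isfinite(self.si_segments))
        ):
            raise ValidationError("fluorescence values must be finite and >= 0")

    @property
    def total(self) -> float:
        return float(self.stomach + self.si_segments.sum() + self.colon)


def gastric_emptying_rate(profile: TransitProfile) -> float:
    """Gastric emptying = (total recovered − stomach) / total × 100%."""
    total = profile.total
    if total <= 0:
        raise ValidationError("total recovered fluorescence must be positive")
    return (total - profile.stomach) / total * 100.0


def geometric_center(profile: TransitProfile) -> float:
    """Fluorescence-weighted mean segment index, in [1, 10].

    For segment i (1..10), a_i = f_i · i / Σf; the geometric center is
    Σ a_i.  1 indicates minimal and 10 maximal small-intestinal motility.
    """
    f = profile.si_segments
    total_si = f.sum()
    if total_si <= 0:
        raise ValidationError("no fluorescence recovered in the small intestine")
    segments = np.arange(1, N_SI_SEGMENTS + 1)
    return float(np.sum(f * segments) / total_si)


def colon_travel_fraction(dye_distance: float, colon_length: float) -> float:
    """Dye travel distance in the colon as % of full colon length."""
    if colon_length <= 0:
        raise ValidationError("colon length must be positive")
    if dye_distance < 0 or dye_distance > colon_length:
        raise ValidationError("dye distance must lie within [0, colon length]")
    return dye_distance / colon_length * 100.0


def qpcr_relative_expression(
    ct_table: pd.DataFrame,
    reference_group: str,
    housekeeping: tuple[str, ...] = DEFAULT_HOUSEKEEPING,
    aggregate: str = "arithmetic",
) -> pd.DataFrame:
    """ΔΔCt fold-changes relative to a reference group.

    ΔCt(gene, sample) = Ct(gene) − aggregate Ct of the housekeeping genes
    within the same sample (arithmetic mean by default, geometric mean of
    efficiencies via ``aggregate='geometric'`` operates on 2^−Ct).
    Fold-change(gene, group) = 2^−(mean ΔCt(group) − mean ΔCt(reference)).
    The reference group maps to 1 exactly.
    """
    required = {"gene", "sample", "group", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValidationError(f"Ct table needs columns {sorted(required)}")
    if reference_group not in set(ct_table["group"]):
        raise ValidationError(f"reference group {reference_group!r} absent")

    hk = set(housekeeping)
    hk_ct: dict[str, float] = {}
    for sample, sub in ct_table.groupby("sample"):
        have = set(sub["gene"]) & hk
        if have != hk:
            missing = sorted(hk - have)
            raise ValidationError(
                f"sample {sample!r} is missing housekeeping genes {missing}"
            )
        vals = sub[sub["gene"].isin(hk)]["ct"].astype(float)
        if aggregate == "geometric":
            hk_ct[sample] = float(-np.log2(np.mean(2.0 ** (-vals))))
        else:
            hk_ct[sample] = float(vals.mean())

    df = ct_table[~ct_table["gene"].isin(hk)].copy()
    df["ct"] = df["ct"].astype(float)
    df["delta_ct"] = df["ct"] - df["sample"].map(hk_ct)
    mean_dct = df.groupby(["gene", "group"])["delta_ct"].mean().unstack("group")
    ref = mean_dct[reference_group]
    fc = 2.0 ** -(mean_dct.sub(ref, axis=0))
    fc.columns.name = "group"
    return fc


def summarize_measurements(x, y) -> pd.DataFrame:
    """Mean/SD summary plus an unpaired t-test for two recorded-measurement
    groups (whole-gut transit time, bead-expulsion latency, ...)."""
    from .stats_core import t_test_unpaired

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = t_test_unpaired(x, y)
    return pd.DataFrame(
        {
            "group": ["x", "y"],
            "n": [x.size, y.size],
            "mean": [x.mean(), y.mean()],
            "sd": [x.std(ddof=1), y.std(ddof=1)],
            "t": [res.statistic] * 2,
            "p": [res.p_value] * 2,
        }
    )
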
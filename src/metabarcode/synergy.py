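"""Plate-level synergy statistics: survival rates, combination index Q,
and the Bliss-independence t-test.

From a viability plate (optical density at 490 nm) the per-group survival
rate is OD_treatment / OD_control and the inhibitory rate E = 1 - survival.
Two complementary synergy read-outs are computed per dose pair:

* combination index  Q = E_combo / (E_a + E_b - E_a * E_b), the observed
  combined inhibition over its Bliss-independence expectation (Q = 1 is
  exact additivity; Q >= 1.15 is read as synergy);
* a pooled-variance t-test on per-well log survival, contrast
  ybar_a + ybar_b - ybar_combo, df = sum(n_i) - 3, which is zero in
  expectation exactly under Bliss independence (survival multiplies).

The verdict "synergistic" requires Q >= 1.15, two-sided p < 0.05, and
t > 0 (the synergy direction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("control", "drug_a", "drug_b", "combination")
DEFAULT_Q_THRESHOLD = 1.15
DEFAULT_ALPHA = 0.05

PLATE_COLUMNS = ["group", "dose_a_uM", "dose_b_uM", "replicate", "od490"]


@dataclass(frozen=True)
class SynergyResult:
    """Joint Q / Bliss-t verdict for one dose pair."""

    q: float
    t: float
    df: int
    p: float
    synergistic: bool


def rates_from_od(plate: pd.DataFrame, convention: str = "standard") -> pd.DataFrame:
    """Per-group survival and inhibitory rates from a plate table.

    ``standard``: survival = mean OD_treatment / mean OD_control (untreated
    wells survive at rate 1). ``printed`` keeps the alternative convention
    in which the same ratio is read as 1 - survival. Rates outside (0, 1)
    are clipped with a warning. Requires a ``control`` group.
    """
    if convention not in ("standard", "printed"):
        raise ValueError("convention must be 'standard' or 'printed'")
    if (plate["od490"] <= 0).any():
        raise ValueError("optical densities must be positive")
    means = plate.groupby("group")["od490"].mean()
    if "control" not in means.index:
        raise ValueError("plate has no control group")
    rows = []
    for group, od in means.items():
        ratio = od / means["control"]
        survival = ratio if convention == "standard" else 1.0 - ratio
        if group != "control" and not 0.0 < survival <= 1.0:
            warnings.warn(
                f"group {group!r}: survival {survival:.4f} outside (0,1); clipped",
                stacklevel=2,
            )
            survival = float(np.clip(survival, 1e-6, 1.0 - 1e-6))
        rows.append(
            {"group": group, "survival_rate": survival, "inhibitory_rate": 1.0 - survival}
        )
    return pd.DataFrame(rows).set_index("group")


def combination_q(e_combo: float, e_a: float, e_b: float) -> float:
    """Combination index Q = E_combo / (E_a + E_b - E_a * E_b)."""
    for name, e in (("e_combo", e_combo), ("e_a", e_a), ("e_b", e_b)):
        if not 0.0 <= e < 1.0:
            raise ValueError(f"{name} must lie in [0, 1), got {e}")
    denom = e_a + e_b - e_a * e_b
    if denom <= 0.0:
        raise ValueError("Bliss expectation is zero: both single agents inert")
    return e_combo / denom


def log_survival_groups(plate: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-well log survival for the three treated groups.

    y_ij = log(OD_ij / mean control OD); the control-normalizing constant
    is treated as fixed. Zero/negative survival is impossible for positive
    ODs but ratios are validated anyway.
    """
    control_mean = plate.loc[plate["group"] == "control", "od490"].mean()
    if not np.isfinite(control_mean) or control_mean <= 0:
        raise ValueError("plate has no usable control group")
    out: dict[str, np.ndarray] = {}
    for group in ("drug_a", "drug_b", "combination"):
        od = plate.loc[plate["group"] == group, "od490"].to_numpy(dtype=float)
        if od.size < 2:
            raise ValueError(f"group {group!r} needs >= 2 replicate wells")
        if np.any(od <= 0):
            raise ValueError(f"group {group!r} has non-positive OD")
        out[group] = np.log(od / control_mean)
    return out


def bliss_t_test(
    y1: np.ndarray, y2: np.ndarray, y3: np.ndarray
) -> tuple[float, int, float]:
    """Pooled-variance t for the Bliss contrast on log survival.

    t = (ybar1 + ybar2 - ybar3) / (s_p * sqrt(1/n1 + 1/n2 + 1/n3)) with
    s_p^2 pooled over the three groups on df = n1 + n2 + n3 - 3; two-sided
    p from Student's t. Positive t means stronger-than-Bliss killing.
    """
    ys = [np.asarray(y, dtype=float) for y in (y1, y2, y3)]
    if any(y.size < 2 for y in ys):
        raise ValueError("each group needs >= 2 replicates")
    ns = [y.size for y in ys]
    df = sum(ns) - 3
    contrast = ys[0].mean() + ys[1].mean() - ys[2].mean()
    ss = sum(float(((y - y.mean()) ** 2).sum()) for y in ys)
    sp2 = ss / df
    scale = np.sqrt(sum(1.0 / n for n in ns))
    if sp2 == 0.0:
        if contrast == 0.0:
            return 0.0, df, 1.0
        warnings.warn("zero pooled variance with nonzero contrast; p set to 0", stacklevel=2)
        return float(np.sign(contrast)) * np.inf, df, 0.0
    t = contrast / (np.sqrt(sp2) * scale)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), df, p


def synergy_verdict(
    q: float,
    t: float,
    df: int,
    p: float,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> SynergyResult:
    """Joint rule: synergistic iff Q >= threshold (inclusive), p < alpha, t > 0."""
    return SynergyResult(
        q=q,
        t=t,
        df=df,
        p=p,
        synergistic=bool(q >= q_threshold and p < alpha and t > 0.0),
    )


def evaluate_plate(
    plate: pd.DataFrame,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    convention: str = "standard",
) -> SynergyResult:
    """Full single-dose-pair evaluation: rates -> Q, log survival -> t, verdict."""
    rates = rates_from_od(plate, convention=convention)
    for group in GROUPS:
        if group not in rates.index:
            raise ValueError(f"plate is missing group {group!r}")
    q = combination_q(
        rates.loc["combination", "inhibitory_rate"],
        rates.loc["drug_a", "inhibitory_rate"],
        rates.loc["drug_b", "inhibitory_rate"],
    )
    ys = log_survival_groups(plate)
    t, df, p = bliss_t_test(ys["drug_a"], ys["drug_b"], ys["combination"])
    return synergy_verdict(q, t, df, p, q_threshold=q_threshold, alpha=alpha)


def synergy_table(
    plate: pd.DataFrame,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    convention: str = "standard",
) -> pd.DataFrame:
    """Evaluate every combination dose pair on a multi-dose plate.

    For each (dose_a, dose_b) present in the ``combination`` group, the
    matching single-agent groups (drug_a at dose_a, drug_b at dose_b) and
    the shared control are assembled into a one-pair plate and evaluated.
    """
    combos = (
        plate.loc[plate["group"] == "combination", ["dose_a_uM", "dose_b_uM"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    control = plate[plate["group"] == "control"]
    rows = []
    for dose_a, dose_b in combos:
        sub = pd.concat(
            [
                control,
                plate[(plate["group"] == "drug_a") & (plate["dose_a_uM"] == dose_a)],
                plate[(plate["group"] == "drug_b") & (plate["dose_b_uM"] == dose_b)],
                plate[
                    (plate["group"] == "combination")
                    & (plate["dose_a_uM"] == dose_a)
                    & (plate["dose_b_uM"] == dose_b)
                ],
            ]
        )
        res = evaluate_plate(
            sub, q_threshold=q_threshold, alpha=alpha, convention=convention
        )
        rates = rates_from_od(sub, convention=convention)
        rows.append(
            {
                "dose_a_uM": dose_a,
                "dose_b_uM": dose_b,
                "e_a": rates.loc["drug_a", "inhibitory_rate"],
                "e_b": rates.loc["drug_b", "inhibitory_rate"],
                "e_combo": rates.loc["combination", "inhibitory_rate"],
                "q": res.q,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "synergistic": res.synergistic,
            }
        )
    return pd.DataFrame(rows)
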
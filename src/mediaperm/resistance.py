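"""Decomposition of arterial-wall hydraulic resistance into layers.

The wall layers act as resistances in series. Total wall resistance comes
from the measured hydraulic conductance, R_WALL = 1 / Lp; the medial
contribution follows from the homogenised radial permeability and medial
thickness, R_MED = mu * T / K11; and the intimal (endothelium +
subendothelial) contribution is the remainder, R_INT = R_WALL - R_MED.
Group statistics (mean +/- SEM, two-sided t-tests, paired where specimen
identities match across conditions) and a +/-20% ECM-permeability
sensitivity sweep complete the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SpecimenRecord", "LayerResistances", "GroupSummary",
           "decompose_resistance", "summarize_groups", "kecm_sensitivity",
           "DEFAULT_MU"]

DEFAULT_MU = 6.913e-4  # Pa s, water at 37 C
UM_TO_M = 1e-6


@dataclass(frozen=True)
class SpecimenRecord:
    """One specimen: measured conductance plus image/simulation-derived
    medial geometry and permeability. Units: lp in m s^-1 Pa^-1,
    thickness in um, k11 in m^2."""

    specimen_id: str
    condition: str  # 'baseline' | 'constricted'
    lp: float
    thickness_um: float
    k11: float

    def validate(self) -> None:
        if self.lp <= 0:
            raise ValueError(f"{self.specimen_id}: lp must be positive")
        if self.thickness_um <= 0:
            raise ValueError(f"{self.specimen_id}: thickness must be positive")
        if self.k11 <= 0:
            raise ValueError(f"{self.specimen_id}: k11 must be positive")


@dataclass
class LayerResistances:
    """Wall, medial and intimal resistances (Pa s m^-1) of one specimen;
    additivity r_wall = r_med + r_int holds by construction."""

    r_wall: float
    r_med: float
    r_int: float

    @property
    def fractions(self) -> tuple[float, float]:
        """(medial, intimal) fractions of wall resistance; they sum to 1."""
        return self.r_med / self.r_wall, self.r_int / self.r_wall


@dataclass
class GroupSummary:
    quantity: str
    n: tuple[int, int]
    mean: tuple[float, float]
    sem: tuple[float, float]
    test: str  # 'paired t' | 'unpaired t'
    p_value: float
    direction: str  # 'increase' | 'decrease' | 'none'


def decompose_resistance(rec: SpecimenRecord,
                         viscosity_mu: float = DEFAULT_MU) -> LayerResistances:
    """Series decomposition of wall resistance for one specimen.

    A negative intimal resistance (medial resistance exceeding the whole
    wall's) is physically inconsistent; it is reported with a warning
    rather than clamped, so inconsistent inputs stay visible.
    """
    rec.validate()
    if viscosity_mu <= 0:
        raise ValueError("viscosity must be positive")
    r_wall = 1.0 / rec.lp
    r_med = viscosity_mu * (rec.thickness_um * UM_TO_M) / rec.k11
    r_int = r_wall - r_med
    if r_int < 0:
        warnings.warn(
            f"specimen {rec.specimen_id}: R_MED ({r_med:.3g}) exceeds "
            f"R_WALL ({r_wall:.3g}); negative intimal resistance indicates "
            "inconsistent Lp / K11 / thickness inputs", stacklevel=2)
    return LayerResistances(r_wall=r_wall, r_med=r_med, r_int=r_int)


def _group_values(records: list[SpecimenRecord], attr) -> tuple[np.ndarray, np.ndarray, list, list]:
    base = [r for r in records if r.condition == "baseline"]
    cons = [r for r in records if r.condition == "constricted"]
    get = attr if callable(attr) else (lambda r: getattr(r, attr))
    return (np.array([get(r) for r in base]), np.array([get(r) for r in cons]),
            base, cons)


def summarize_groups(records: list[SpecimenRecord],
                     quantities: tuple[str, ...] = ("lp", "thickness_um", "k11"),
                     pairing: str = "auto",
                     equal_var: bool = True) -> dict[str, GroupSummary]:
    """Baseline vs constricted group statistics per quantity.

    SEM uses the n-1 sample standard deviation. The t-test is two-sided;
    it is paired when every specimen id appears in both conditions (or
    pairing='paired' is forced), classical unpaired otherwise
    (equal_var=False switches to the Welch variant).
    """
    out: dict[str, GroupSummary] = {}
    for q in quantities:
        a, b, base, cons = _group_values(records, q)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"{q}: need at least 2 records per group")
        ids_a = [r.specimen_id for r in base]
        ids_b = [r.specimen_id for r in cons]
        paired = pairing == "paired" or (
            pairing == "auto" and len(ids_a) == len(ids_b)
            and set(ids_a) == set(ids_b))
        if pairing == "paired" and set(ids_a) != set(ids_b):
            raise ValueError(f"{q}: paired test requested but specimen ids "
                             "do not match across conditions")
        if paired:
            order = {sid: i for i, sid in enumerate(ids_a)}
            b = b[np.argsort([order[sid] for sid in ids_b])]
            res = stats.ttest_rel(b, a)
            test = "paired t"
        else:
            res = stats.ttest_ind(b, a, equal_var=equal_var)
            test = "unpaired t" if equal_var else "Welch t"
        diff = b.mean() - a.mean()
        out[q] = GroupSummary(
            quantity=q,
            n=(len(a), len(b)),
            mean=(float(a.mean()), float(b.mean())),
            sem=(float(stats.sem(a, ddof=1)), float(stats.sem(b, ddof=1))),
            test=test,
            p_value=float(res.pvalue),
            direction="increase" if diff > 0 else ("decrease" if diff < 0 else "none"),
        )
    return out


def kecm_sensitivity(records: list[SpecimenRecord],
                     viscosity_mu: float = DEFAULT_MU,
                     k_ecm_scalings: tuple[float, ...] = (0.8, 1.0, 1.2),
                     rescale_rule: str = "proportional") -> pd.DataFrame:
    """Sensitivity of the resistance split to the assumed ECM permeability.

    The Brinkman problem is linear in k_ECM at fixed geometry (up to
    penalty effects), so under the default 'proportional' rule K11 scales
    with k_ECM and R_MED scales with its inverse. Returns one row per
    (condition, scaling) with group-mean medial and intimal fractions of
    wall resistance.
    """
    if rescale_rule != "proportional":
        raise ValueError("only the 'proportional' rescale rule is built in; "
                         "re-run the solver with a scaled k_ecm for the "
                         "exact alternative")
    rows = []
    for s in k_ecm_scalings:
        for condition in ("baseline", "constricted"):
            group = [r for r in records if r.condition == condition]
            if not group:
                continue
            med_fracs, int_fracs = [], []
            for r in group:
                scaled = SpecimenRecord(r.specimen_id, r.condition, r.lp,
                                        r.thickness_um, r.k11 * s)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    lr = decompose_resistance(scaled, viscosity_mu)
                mf, intf = lr.fractions
                med_fracs.append(mf)
                int_fracs.append(intf)
            rows.append({"k_ecm_scaling": s, "condition": condition,
                         "r_med_fraction": float(np.mean(med_fracs)),
                         "r_int_fraction": float(np.mean(int_fracs))})
    return pd.DataFrame(rows)


def plot_decomposition(records: list[SpecimenRecord],
                       viscosity_mu: float = DEFAULT_MU, ax=None):
    """Stacked-bar chart of group-mean medial and intimal resistances
    (+/- SEM on the wall total) per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    conditions = [c for c in ("baseline", "constricted")
                  if any(r.condition == c for r in records)]
    meds, ints, sems = [], [], []
    for cond in conditions:
        group = [decompose_resistance(r, viscosity_mu)
                 for r in records if r.condition == cond]
        meds.append(np.mean([g.r_med for g in group]))
        ints.append(np.mean([g.r_int for g in group]))
        walls = [g.r_wall for g in group]
        sems.append(stats.sem(walls) if len(walls) > 1 else 0.0)
    x = np.arange(len(conditions))
    ax.bar(x, meds, label="medial")
    ax.bar(x, ints, bottom=meds, yerr=sems, capsize=4, label="intimal")
    ax.set_xticks(x, conditions)
    ax.set_ylabel("hydraulic resistance (Pa s m$^{-1}$)")
    ax.legend(frameon=False)
    return ax


def records_from_csv(path) -> list[SpecimenRecord]:
    """Load specimens from CSV with columns
    specimen_id, condition, lp, thickness_um, k11."""
    df = pd.read_csv(path, comment="#")
    required = {"specimen_id", "condition", "lp", "thickness_um", "k11"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"specimens CSV missing columns: {sorted(missing)}")
    recs = [SpecimenRecord(str(r.specimen_id), str(r.condition), float(r.lp),
                           float(r.thickness_um), float(r.k11))
            for r in df.itertuples()]
    for r in recs:
        r.validate()
    return recs
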
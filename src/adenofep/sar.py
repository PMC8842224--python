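"""Affinity/selectivity analysis of the binding tables.

Converts fitted Ki values to pKi and to experimental binding free
energies, classifies each compound's receptor-selectivity profile from
which receptors yielded a fitted Ki (as opposed to a single-point percent
displacement), and provides the counting/plotting queries behind the
library's affinity-selectivity analysis.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import DEFAULT_TEMPERATURE_K, GAS_CONSTANT_KCAL
from .dataset import CompoundRecord, CompoundTable, Receptor

__all__ = [
    "ProfileClass",
    "SelectivitySummary",
    "pki",
    "exp_delta_g",
    "classify_profile",
    "fold_selectivity",
    "selectivity_plot_table",
    "count_by_filter",
    "summarize",
    "write_report",
    "plot_selectivity",
]

#: Percent-only cells mean the Ki could not be fitted at the 1 μM test
#: concentration; for selectivity-ratio *bounds* they are treated as
#: Ki > 1000 nM.
PERCENT_KI_BOUND_NM = 1000.0

#: Default "high affinity" cut used in the library's headline counts.
KI_HIGH_NM = 50.0


class ProfileClass(str, enum.Enum):
    A1_SELECTIVE = "A1_selective"
    A2A_SELECTIVE = "A2A_selective"
    DUAL_A1_A2A = "dual_A1_A2A"
    DUAL_A2A_A2B = "dual_A2A_A2B"
    INACTIVE = "inactive"
    OTHER = "other"


#: Receptor whose Ki the ``ki_max`` filter of :func:`count_by_filter`
#: applies to, per profile class.
TARGET_RECEPTOR = {
    ProfileClass.A1_SELECTIVE: Receptor.A1,
    ProfileClass.A2A_SELECTIVE: Receptor.A2A,
    ProfileClass.DUAL_A1_A2A: Receptor.A1,
    ProfileClass.DUAL_A2A_A2B: Receptor.A2A,
}


def pki(ki_nM: float) -> float:
    """pKi = −log10(Ki in molar) for a Ki given in nM."""
    if ki_nM <= 0:
        raise ValueError(f"ki_nM must be positive, got {ki_nM}")
    return 9.0 - math.log10(ki_nM)


def exp_delta_g(
    ki_nM: float, T_kelvin: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Experimental binding free energy ΔG = RT·ln(Ki·10⁻⁹) in kcal/mol.

    Negative for any Ki below 1 M; the assay temperature default is
    298.15 K (incubation at 25 °C).
    """
    if ki_nM <= 0:
        raise ValueError(f"ki_nM must be positive, got {ki_nM}")
    if T_kelvin <= 0:
        raise ValueError(f"T_kelvin must be positive, got {T_kelvin}")
    return GAS_CONSTANT_KCAL * T_kelvin * math.log(ki_nM * 1e-9)


def classify_profile(record: CompoundRecord, ki_high_nM: float = KI_HIGH_NM) -> ProfileClass:
    """Assign the selectivity profile from which receptors have a fitted Ki.

    Rule order (first match wins):

    1. no fitted Ki at any receptor            → inactive
    2. Ki only at A1                           → A1-selective
    3. Ki only at A2A                          → A2A-selective
    4. Ki at A2A and A2B, none at A1/A3        → dual A2A/A2B
    5. Ki at both A1 and A2A                   → dual A1/A2A
    6. anything else                           → other

    The percent magnitude of non-fitted cells is deliberately ignored: a
    compound displacing 41% at 1 μM is no more "active" for
    classification purposes than one displacing 1%.
    """
    q = {r: record.affinities[r].is_quantitative for r in Receptor}
    if not any(q.values()):
        return ProfileClass.INACTIVE
    if q[Receptor.A1] and not (q[Receptor.A2A] or q[Receptor.A2B] or q[Receptor.A3]):
        return ProfileClass.A1_SELECTIVE
    if q[Receptor.A2A] and not (q[Receptor.A1] or q[Receptor.A2B] or q[Receptor.A3]):
        return ProfileClass.A2A_SELECTIVE
    if q[Receptor.A2A] and q[Receptor.A2B] and not (q[Receptor.A1] or q[Receptor.A3]):
        return ProfileClass.DUAL_A2A_A2B
    if q[Receptor.A1] and q[Receptor.A2A]:
        return ProfileClass.DUAL_A1_A2A
    return ProfileClass.OTHER


def fold_selectivity(
    record: CompoundRecord,
    target_receptor: Receptor | str,
    other_receptor: Receptor | str,
    pct_bound_nM: float = PERCENT_KI_BOUND_NM,
) -> tuple[float, bool]:
    """Selectivity ratio Ki(other)/Ki(target).

    When the off-target cell is percent-only its Ki is unmeasurable at
    1 μM, so the ratio is a *lower bound* computed with
    ``pct_bound_nM`` in the numerator; the second return value flags
    this.  Ratios below 1 are legal and returned as-is.
    """
    target = record.affinity(target_receptor)
    other = record.affinity(other_receptor)
    if not target.is_quantitative:
        raise ValueError(
            f"{record.compound_id}: target receptor "
            f"{Receptor(target_receptor).value} has no fitted Ki"
        )
    if other.is_quantitative:
        return other.ki_nM / target.ki_nM, False
    return pct_bound_nM / target.ki_nM, True


def selectivity_plot_table(
    table: CompoundTable, series_filter: Iterable[str] | None = None
) -> pd.DataFrame:
    """Rows for the pKi(A2A) vs pKi(A1) affinity-selectivity plot.

    One row per compound with at least one fitted Ki at A1 or A2A; a
    missing axis value is left as NaN, never zero-filled.
    """
    series = set(series_filter) if series_filter is not None else None
    rows = []
    for rec in table.records:
        if series is not None and rec.series not in series:
            continue
        a1 = rec.affinity(Receptor.A1)
        a2a = rec.affinity(Receptor.A2A)
        if not (a1.is_quantitative or a2a.is_quantitative):
            continue
        rows.append(
            {
                "compound_id": rec.compound_id,
                "pki_A1": pki(a1.ki_nM) if a1.is_quantitative else float("nan"),
                "pki_A2A": pki(a2a.ki_nM) if a2a.is_quantitative else float("nan"),
                "profile": classify_profile(rec).value,
                "r2": rec.r2,
                "r4": rec.r4,
            }
        )
    return pd.DataFrame(
        rows, columns=["compound_id", "pki_A1", "pki_A2A", "profile", "r2", "r4"]
    )


def count_by_filter(
    table: CompoundTable,
    profile: ProfileClass | str,
    series: str | None = None,
    ki_max_nM: float = math.inf,
) -> int:
    """Count library compounds matching profile ∧ series ∧ Ki(target) < cut."""
    profile = ProfileClass(profile)
    target = TARGET_RECEPTOR.get(profile)
    n = 0
    for rec in table.records:
        if series is not None and rec.series != series:
            continue
        if classify_profile(rec) is not profile:
            continue
        if math.isfinite(ki_max_nM) and target is not None:
            if rec.affinity(target).ki_nM >= ki_max_nM:
                continue
        n += 1
    return n


def members_by_filter(
    table: CompoundTable,
    profile: ProfileClass | str,
    series: str | None = None,
    ki_max_nM: float = math.inf,
) -> list[str]:
    """Ids (table order) of compounds matching the same filter as
    :func:`count_by_filter`."""
    profile = ProfileClass(profile)
    target = TARGET_RECEPTOR.get(profile)
    out = []
    for rec in table.records:
        if series is not None and rec.series != series:
            continue
        if classify_profile(rec) is not profile:
            continue
        if math.isfinite(ki_max_nM) and target is not None:
            if rec.affinity(target).ki_nM >= ki_max_nM:
                continue
        out.append(rec.compound_id)
    return out


@dataclass(frozen=True)
class SelectivitySummary:
    compound_id: str
    pki: Mapping[str, float]
    dg_exp_kcal: Mapping[str, float]
    profile: ProfileClass
    fold_a1_over_a2a: float | None
    fold_is_lower_bound: bool


def summarize(
    record: CompoundRecord, T_kelvin: float = DEFAULT_TEMPERATURE_K
) -> SelectivitySummary:
    """Per-compound pKi / ΔG / profile summary (fitted receptors only)."""
    pkis: dict[str, float] = {}
    dgs: dict[str, float] = {}
    for r in Receptor:
        entry = record.affinities[r]
        if entry.is_quantitative:
            pkis[r.value] = pki(entry.ki_nM)
            dgs[r.value] = exp_delta_g(entry.ki_nM, T_kelvin)
    fold = None
    bound = False
    if record.affinity(Receptor.A1).is_quantitative:
        fold, bound = fold_selectivity(record, Receptor.A1, Receptor.A2A)
    return SelectivitySummary(
        compound_id=record.compound_id,
        pki=pkis,
        dg_exp_kcal=dgs,
        profile=classify_profile(record),
        fold_a1_over_a2a=fold,
        fold_is_lower_bound=bound,
    )


def write_report(table: CompoundTable, out_dir: str | Path) -> dict:
    """Write the SAR summary (JSON headline counts + per-compound CSV).

    Returns the headline-count dictionary.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = {
        "library_size": len(table),
        "series_counts": table.series_counts(),
        "a1_selective_high_affinity_series_II": count_by_filter(
            table, ProfileClass.A1_SELECTIVE, "II", KI_HIGH_NM
        ),
        "a1_selective_high_affinity_ids": members_by_filter(
            table, ProfileClass.A1_SELECTIVE, "II", KI_HIGH_NM
        ),
        "a2a_selective_series_II": count_by_filter(
            table, ProfileClass.A2A_SELECTIVE, "II"
        ),
        "a2a_selective_ids": members_by_filter(table, ProfileClass.A2A_SELECTIVE, "II"),
        "dual_a2a_a2b_series_II": count_by_filter(
            table, ProfileClass.DUAL_A2A_A2B, "II"
        ),
        "dual_a2a_a2b_ids": members_by_filter(table, ProfileClass.DUAL_A2A_A2B, "II"),
    }
    with open(out_dir / "sar_summary.json", "w") as fh:
        json.dump(counts, fh, indent=2)
    selectivity_plot_table(table).to_csv(out_dir / "selectivity_table.csv", index=False)
    return counts


def plot_selectivity(
    table: CompoundTable,
    path: str | Path,
    series_filter: Iterable[str] | None = None,
) -> None:
    """Render the affinity-selectivity scatter (pKi A2A vs pKi A1) to SVG/PNG.

    Marker encodes the R2 amine, color the profile class; compounds with a
    single fitted axis are pinned to the plot margin band.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = selectivity_plot_table(table, series_filter)
    markers = {"NH2": "o", "NHMe": "s", "NHEt": "*", "NHPh": "^", "NMe2": "D"}
    fig, ax = plt.subplots(figsize=(6, 6))
    floor = 5.7  # pKi of the 1 uM measurability bound, minus margin
    for r2, m in markers.items():
        sub = df[df.r2 == r2]
        if sub.empty:
            continue
        x = sub.pki_A1.fillna(floor)
        y = sub.pki_A2A.fillna(floor)
        ax.scatter(x, y, marker=m, label=r2, alpha=0.75)
    lim = (5.5, 9.5)
    ax.plot(lim, lim, color="gray", lw=0.8, ls="--")
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    ax.set_xlabel("pKi A1AR")
    ax.set_ylabel("pKi A2AAR")
    ax.legend(title="R2", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
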
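"""Time-weighted dosimetric variation from posture statistics and SAR.

The influence of a neighbouring animal is expressed per posture case as a
variation rate

    eta_i = (S_1i - S_1) / S_1 * 100%

where ``S_1i`` is rat 1's whole-body average SAR with the neighbour in
case ``i`` and ``S_1`` the single-animal reference, and aggregated over
the recording as the occupancy-weighted average

    eta_avg = sum_i W_i * eta_i .

The 25 closely-huddled cases (d = 0 block) share one simulated SAR value,
so a SAR table may carry only case 1 for that block; it is broadcast to
cases 2-25 here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .posture import N_CASES, PostureDistribution, case_label, indices_from_case_id


class MissingCaseError(ValueError):
    """Cases observed in the video lack a SAR table entry."""

    def __init__(self, case_ids: list[int]) -> None:
        self.case_ids = case_ids
        super().__init__(
            f"SAR table has no entry for occupied case(s): {case_ids}")


def variation_rate(s1i: float | np.ndarray, s1: float) -> float | np.ndarray:
    """Percent change of WB-avgSAR relative to the single-animal reference."""
    if s1 <= 0:
        raise ValueError(f"reference SAR must be positive, got {s1}")
    return (np.asarray(s1i, dtype=float) - s1) / s1 * 100.0


def average_variation(dist: PostureDistribution, eta: np.ndarray) -> float:
    """Occupancy-weighted average variation rate (percent)."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (N_CASES,):
        raise ValueError(f"eta must have shape ({N_CASES},), got {eta.shape}")
    w = dist.weights
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("distribution weights must sum to 1")
    bad = np.nonzero((w > 0) & ~np.isfinite(eta))[0]
    if bad.size:
        raise MissingCaseError([int(i) + 1 for i in bad])
    return float(np.dot(w, np.where(np.isfinite(eta), eta, 0.0)))


@dataclass(frozen=True)
class VariationReport:
    """Full per-case and aggregate dosimetric variation."""

    s1: float
    s1i: np.ndarray
    eta: np.ndarray
    eta_avg: float
    distribution: PostureDistribution

    def __post_init__(self) -> None:
        if self.s1 <= 0:
            raise ValueError("reference SAR must be positive")

    @property
    def eta_avg_magnitude(self) -> float:
        return abs(self.eta_avg)

    def per_case_table(self) -> pd.DataFrame:
        rows = []
        for cid in range(1, N_CASES + 1):
            d_lab, a_lab, b_lab = case_label(cid)
            rows.append(
                {"case_id": cid, "d_label": d_lab, "alpha_label": a_lab,
                 "beta_label": b_lab, "W": self.distribution.weights[cid - 1],
                 "S1i_w_kg": self.s1i[cid - 1], "eta_pct": self.eta[cid - 1]}
            )
        return pd.DataFrame(rows)

    def summary_text(self) -> str:
        occ = int((self.distribution.weights > 0).sum())
        lines = [
            "Whole-body average SAR variation due to a neighbouring animal",
            f"  reference S1             : {self.s1:.6g} W/kg",
            f"  frames analysed          : "
            f"{self.distribution.frame_count or 'n/a'}",
            f"  posture cases occupied   : {occ} / {N_CASES}",
            f"  P(d = 0 super-case)      : "
            f"{self.distribution.weights[:25].sum() * 100:.2f} %",
            f"  eta_avg (signed)         : {self.eta_avg:+.3f} %",
            f"  eta_avg (magnitude)      : {self.eta_avg_magnitude:.3f} %",
        ]
        return "\n".join(lines)


def expand_supercase(sar_table: pd.DataFrame) -> pd.DataFrame:
    """Broadcast a lone case-1 SAR entry over the merged d = 0 block."""
    tab = sar_table.copy()
    have = set(tab["case_id"].astype(int))
    if 1 in have:
        row1 = tab.loc[tab["case_id"] == 1].iloc[0]
        add = []
        for cid in range(2, 26):
            if cid not in have:
                r = row1.copy()
                r["case_id"] = cid
                add.append(r)
        if add:
            tab = pd.concat([tab, pd.DataFrame(add)], ignore_index=True)
    return tab


def build_report(
    distribution: PostureDistribution,
    sar_table: pd.DataFrame,
    reference_s1: float,
    sar_column: str = "sar_1",
) -> VariationReport:
    """Combine occupancy W, per-case SAR and the reference into the report.

    ``sar_table`` needs columns ``case_id`` and ``sar_column``.  Any case
    with W_i > 0 but no SAR entry (after d = 0 broadcasting) raises
    :class:`MissingCaseError` naming the offenders.
    """
    if reference_s1 <= 0:
        raise ValueError("reference SAR must be positive")
    tab = expand_supercase(sar_table)
    s1i = np.full(N_CASES, np.nan)
    for _, row in tab.iterrows():
        cid = int(row["case_id"])
        indices_from_case_id(cid)  # range check
        s1i[cid - 1] = float(row[sar_column])
    w = distribution.weights
    missing = [int(i) + 1 for i in np.nonzero((w > 0) & np.isnan(s1i))[0]]
    if missing:
        raise MissingCaseError(missing)
    eta = np.where(np.isnan(s1i), np.nan,
                   variation_rate(np.nan_to_num(s1i), reference_s1))
    eta_avg = average_variation(distribution, eta)
    return VariationReport(s1=reference_s1, s1i=s1i, eta=eta,
                           eta_avg=eta_avg, distribution=distribution)
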
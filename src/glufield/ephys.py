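"""Quantal analysis of two-electrode voltage-clamp amplitude tables.

The module starts from event amplitudes (mEPSC, eEPSC and paired-pulse
pairs) rather than raw current traces. Cells are screened by the standard
health criteria (initial membrane potential at least −50 mV, membrane
resistance ≥ 4 MΩ). Minis are recorded at a −80 mV holding potential and
evoked currents at −60 mV, so before dividing, mini amplitudes are scaled
to −60 mV assuming a 0 mV reversal potential and an ohmic current–voltage
relationship — a factor of exactly 0.75 for −80 → −60. Quantal content is
then the mean evoked amplitude over the mean scaled mini amplitude of the
same cell, and the paired-pulse ratio is the ratio of the averaged second
to the averaged first response at a 30 ms interstimulus interval.

Amplitudes are stored signed (inward currents negative); every derived
ratio is invariant to flipping the sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, FormatError, ParameterError

__all__ = [
    "EphysCell",
    "QuantalResult",
    "include_cell",
    "scale_mepsc",
    "quantal_content",
    "paired_pulse_ratio",
    "simulate_cells",
    "QuantalContentEstimator",
    "load_cells",
    "write_cells",
]

VM_MAX_MV = -50.0  # initial membrane potential must be at least this hyperpolarized
RM_MIN_MOHM = 4.0  # minimum membrane resistance
HOLD_MEPSC_MV = -80.0
HOLD_EEPSC_MV = -60.0
E_REV_MV = 0.0
PPR_IPI_MS = 30.0


@dataclass(frozen=True)
class EphysCell:
    """One muscle cell's recording summary (amplitudes in nA, signed)."""

    cell_id: str
    vm: float  # initial membrane potential, mV
    rm: float  # membrane resistance, MΩ
    mepsc_amps: tuple[float, ...] = ()
    eepsc_amps: tuple[float, ...] = ()
    ppr_pairs: tuple[tuple[float, float], ...] = ()
    hold_m: float = HOLD_MEPSC_MV
    hold_e: float = HOLD_EEPSC_MV
    ipi: float = PPR_IPI_MS
    condition: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "mepsc_amps", tuple(float(a) for a in self.mepsc_amps))
        object.__setattr__(self, "eepsc_amps", tuple(float(a) for a in self.eepsc_amps))
        object.__setattr__(
            self, "ppr_pairs", tuple((float(a), float(b)) for a, b in self.ppr_pairs)
        )


@dataclass(frozen=True)
class QuantalResult:
    """Derived per-cell measures."""

    cell_id: str
    mean_eepsc: float  # nA, at hold_e
    mean_mepsc_scaled: float  # nA, scaled to hold_e
    quantal_content: float
    ppr: float | None = None


def include_cell(cell: EphysCell, vm_max: float = VM_MAX_MV, rm_min: float = RM_MIN_MOHM) -> bool:
    """Health screen: keep cells with vm ≤ vm_max and rm ≥ rm_min.

    Both thresholds are inclusive; a cell at exactly −50 mV and 4 MΩ
    passes. Missing vm or rm is a validation error, not an exclusion.
    """
    if cell.vm is None or cell.rm is None or not np.isfinite([cell.vm, cell.rm]).all():
        raise ParameterError(f"cell {cell.cell_id!r}: vm/rm missing or non-finite")
    return cell.vm <= vm_max and cell.rm >= rm_min


def scale_mepsc(
    amp: float,
    hold_m: float = HOLD_MEPSC_MV,
    target: float = HOLD_EEPSC_MV,
    e_rev: float = E_REV_MV,
) -> float:
    """Scale an amplitude between holding potentials, assuming ohmic I–V.

    ``amp × (target − e_rev) / (hold_m − e_rev)``; for −80 → −60 mV with a
    0 mV reversal this multiplies by exactly 0.75.
    """
    if hold_m == e_rev:
        raise ParameterError("holding potential equals the reversal potential")
    return amp * (target - e_rev) / (hold_m - e_rev)


def quantal_content(cell: EphysCell) -> QuantalResult:
    """Mean evoked over mean scaled mini amplitude of one cell."""
    if not cell.eepsc_amps or not cell.mepsc_amps:
        raise EmptyInputError(f"cell {cell.cell_id!r}: needs >= 1 eEPSC and >= 1 mEPSC")
    mean_e = float(np.mean(cell.eepsc_amps))
    mean_m = scale_mepsc(float(np.mean(cell.mepsc_amps)), cell.hold_m, cell.hold_e)
    if mean_m == 0.0:
        raise ParameterError(f"cell {cell.cell_id!r}: zero mean mEPSC amplitude")
    ppr = paired_pulse_ratio(cell.ppr_pairs) if cell.ppr_pairs else None
    return QuantalResult(
        cell_id=cell.cell_id,
        mean_eepsc=mean_e,
        mean_mepsc_scaled=mean_m,
        quantal_content=mean_e / mean_m,
        ppr=ppr,
    )


def paired_pulse_ratio(pairs: Sequence[tuple[float, float]]) -> float:
    """Mean second amplitude over mean first amplitude (averaged traces)."""
    if not len(pairs):
        raise EmptyInputError("paired_pulse_ratio needs >= 1 amplitude pair")
    arr = np.asarray(pairs, dtype=float)
    a1 = float(arr[:, 0].mean())
    a2 = float(arr[:, 1].mean())
    if a1 == 0.0:
        raise ParameterError("zero mean first-pulse amplitude")
    return a2 / a1


def simulate_cells(
    n_cells: int = 10,
    true_qc: float = 50.0,
    mepsc_mu: float = -0.8,
    cv: float = 0.1,
    true_ppr: float = 1.2,
    n_mepsc: int = 50,
    n_eepsc: int = 10,
    n_ppr: int = 8,
    seed: int = 0,
) -> list[EphysCell]:
    """Generate synthetic cells with a known quantal content.

    Every mini amplitude is ``mepsc_mu × (1 + ε)`` and every evoked
    amplitude ``true_qc × 0.75 × mepsc_mu × (1 + ε)`` with independent
    Gaussian noise of coefficient of variation ``cv``, so at cv = 0 the
    per-cell estimate equals ``true_qc`` exactly. vm/rm are drawn well
    inside the inclusion window.
    """
    if n_cells < 1 or n_mepsc < 1 or n_eepsc < 1:
        raise ParameterError("counts must be >= 1")
    if cv < 0:
        raise ParameterError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    scale = scale_mepsc(1.0)  # 0.75 for the default holding potentials
    cells = []
    for k in range(n_cells):
        m = mepsc_mu * (1.0 + cv * rng.standard_normal(n_mepsc))
        e = true_qc * scale * mepsc_mu * (1.0 + cv * rng.standard_normal(n_eepsc))
        a1 = true_qc * scale * mepsc_mu * (1.0 + cv * rng.standard_normal(n_ppr))
        a2 = true_ppr * true_qc * scale * mepsc_mu * (1.0 + cv * rng.standard_normal(n_ppr))
        cells.append(
            EphysCell(
                cell_id=f"cell{k:03d}",
                vm=float(rng.uniform(-70.0, -60.0)),
                rm=float(rng.uniform(5.0, 10.0)),
                mepsc_amps=tuple(m),
                eepsc_amps=tuple(e),
                ppr_pairs=tuple(zip(a1, a2)),
            )
        )
    return cells


class QuantalContentEstimator:
    """Per-cell quantal analysis over a cohort, estimator-style.

    ``fit(cells)`` screens cells with :func:`include_cell` and computes
    per-cell quantal content and paired-pulse ratio; summary attributes
    follow the scikit-learn trailing-underscore convention.

    Attributes
    ----------
    results_ : list[QuantalResult]
        Per included cell.
    included_ : list[EphysCell]
    excluded_ : list[EphysCell]
    quantal_contents_ : np.ndarray
    mean_quantal_content_ : float
    pprs_ : np.ndarray
        Paired-pulse ratios of cells that have pairs (possibly empty).
    """

    def __init__(self, vm_max: float = VM_MAX_MV, rm_min: float = RM_MIN_MOHM):
        self.vm_max = vm_max
        self.rm_min = rm_min

    def get_params(self, deep: bool = True) -> dict:
        return {"vm_max": self.vm_max, "rm_min": self.rm_min}

    def set_params(self, **params) -> "QuantalContentEstimator":
        for k, v in params.items():
            if k not in self.get_params():
                raise ParameterError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, cells: Sequence[EphysCell], y=None) -> "QuantalContentEstimator":
        if not len(cells):
            raise EmptyInputError("no cells to analyze")
        self.included_ = [c for c in cells if include_cell(c, self.vm_max, self.rm_min)]
        self.excluded_ = [c for c in cells if c not in self.included_]
        if not self.included_:
            raise EmptyInputError("all cells fail the inclusion criteria")
        self.results_ = [quantal_content(c) for c in self.included_]
        self.quantal_contents_ = np.array([r.quantal_content for r in self.results_])
        self.mean_quantal_content_ = float(self.quantal_contents_.mean())
        self.pprs_ = np.array([r.ppr for r in self.results_ if r.ppr is not None])
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cell_id": r.cell_id,
                    "mean_eepsc_nA": r.mean_eepsc,
                    "mean_mepsc_scaled_nA": r.mean_mepsc_scaled,
                    "quantal_content": r.quantal_content,
                    "ppr": r.ppr,
                }
                for r in self.results_
            ]
        )


def load_cells(cells_csv: str | Path, events_csv: str | Path) -> list[EphysCell]:
    """Assemble cells from the two-table CSV layout.

    ``cells_csv``: ``cell_id, vm_mV, rm_MOhm[, condition]``.
    ``events_csv``: ``cell_id, kind, amplitude_nA[, hold_mV, pair_index]``
    with ``kind`` in {mepsc, eepsc, ppr1, ppr2}; ppr events are matched by
    ``pair_index``.
    """
    cells_df = pd.read_csv(cells_csv)
    events = pd.read_csv(events_csv)
    for col in ("cell_id", "vm_mV", "rm_MOhm"):
        if col not in cells_df.columns:
            raise FormatError(f"cells table lacks column {col!r}")
    for col in ("cell_id", "kind", "amplitude_nA"):
        if col not in events.columns:
            raise FormatError(f"events table lacks column {col!r}")
    cells = []
    for _, row in cells_df.iterrows():
        ev = events[events["cell_id"] == row["cell_id"]]
        m = tuple(ev.loc[ev["kind"] == "mepsc", "amplitude_nA"])
        e = tuple(ev.loc[ev["kind"] == "eepsc", "amplitude_nA"])
        pairs = []
        p1 = ev[ev["kind"] == "ppr1"]
        p2 = ev[ev["kind"] == "ppr2"]
        if len(p1) and "pair_index" in ev.columns:
            for pi in sorted(p1["pair_index"].dropna().unique()):
                a1 = p1.loc[p1["pair_index"] == pi, "amplitude_nA"]
                a2 = p2.loc[p2["pair_index"] == pi, "amplitude_nA"]
                if len(a1) == 1 and len(a2) == 1:
                    pairs.append((float(a1.iloc[0]), float(a2.iloc[0])))
        cells.append(
            EphysCell(
                cell_id=str(row["cell_id"]),
                vm=float(row["vm_mV"]),
                rm=float(row["rm_MOhm"]),
                mepsc_amps=m,
                eepsc_amps=e,
                ppr_pairs=tuple(pairs),
                condition=str(row.get("condition", "")),
            )
        )
    if not cells:
        raise EmptyInputError("cells table is empty")
    return cells


def write_cells(cells: Sequence[EphysCell], cells_csv: str | Path, events_csv: str | Path) -> None:
    """Inverse of :func:`load_cells`."""
    crows, erows = [], []
    for c in cells:
        crows.append(
            {"cell_id": c.cell_id, "vm_mV": c.vm, "rm_MOhm": c.rm, "condition": c.condition}
        )
        for a in c.mepsc_amps:
            erows.append(
                {"cell_id": c.cell_id, "kind": "mepsc", "amplitude_nA": a,
                 "hold_mV": c.hold_m, "pair_index": ""}
            )
        for a in c.eepsc_amps:
            erows.append(
                {"cell_id": c.cell_id, "kind": "eepsc", "amplitude_nA": a,
                 "hold_mV": c.hold_e, "pair_index": ""}
            )
        for k, (a1, a2) in enumerate(c.ppr_pairs):
            erows.append(
                {"cell_id": c.cell_id, "kind": "ppr1", "amplitude_nA": a1,
                 "hold_mV": c.hold_e, "pair_index": k}
            )
            erows.append(
                {"cell_id": c.cell_id, "kind": "ppr2", "amplitude_nA": a2,
                 "hold_mV": c.hold_e, "pair_index": k}
            )
    pd.DataFrame(crows).to_csv(cells_csv, index=False)
    pd.DataFrame(erows).to_csv(events_csv, index=False)
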
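"""Assembly of enthalpies and entropies into transfer free energies and logP.

The octanol–water partition coefficient follows from the transfer free
energy of solute X between four independent simulation boxes,

    ΔG_transfer = (G_X(oct) + G_wat) − (G_oct + G_X(aq)),
    logP = −ΔG_transfer / (ln 10 · k_B T),

with G = H − TS for each box.  H is the mean total (potential + kinetic)
energy; the small pressure–volume term is neglected.  S is the multiscale
sum of components: for an aqueous solution

    S_X(aq) = S_X,M^transvib + S_X,M^rovib + S_X^pos + S_X^or
            + S_X,UA^transvib + S_X,UA^rovib + S_X^conf
            + N_c,X (S_wat,M^transvib + S_wat,M^rovib + S_wat^or)

and for octanol the solvent bracket additionally carries the octanol
united-atom and conformational terms.  Pure-liquid boxes keep the same
N_c,X solvent count to balance stoichiometry.  Solvent terms are
per-molecule entropies; N_c,X enters as the mean coordination number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .constants import J_TO_KCAL, KB_KCAL
from .md_io import EnergySeries

__all__ = [
    "SOLUTE_SLOTS",
    "SOLVENT_SLOTS",
    "SystemResult",
    "TransferSummary",
    "mean_enthalpy",
    "solution_entropy",
    "transfer",
    "logp_from_delta_g",
    "performance_metrics",
    "replicate_sem",
    "load_reference_table",
]

#: solute entropy slots required of every solution box (J/K/mol each)
SOLUTE_SLOTS = ("M_transvib", "M_rovib", "pos", "or",
                "UA_transvib", "UA_rovib", "conf")

#: per-molecule solvent slots: water stops at the molecule level, octanol
#: adds united-atom vibration and conformational terms
SOLVENT_SLOTS = {
    "water": ("M_transvib", "M_rovib", "or"),
    "octanol": ("M_transvib", "M_rovib", "or",
                "UA_transvib", "UA_rovib", "conf"),
}


@dataclass
class SystemResult:
    """Enthalpy and entropy breakdown of one simulation box."""

    label: str                    # X(aq) | X(oct) | wat | oct
    temperature: float            # K
    enthalpy: float               # kcal/mol, mean total energy
    solvent_kind: str             # 'water' | 'octanol'
    solvent_terms: dict[str, float]   # per-molecule entropies, J/K/mol
    mean_nc: float = 0.0          # mean first-shell coordination number
    solute_terms: dict[str, float] | None = None  # None for pure liquids
    extras: dict = field(default_factory=dict)

    @property
    def is_solution(self) -> bool:
        return self.solute_terms is not None


def mean_enthalpy(energy_series: EnergySeries) -> float:
    """Mean per-frame total energy, kcal/mol (NaNs are a hard error)."""
    if np.any(np.isnan(energy_series.values)):
        raise ValueError(f"NaN in energy series '{energy_series.label}'")
    return energy_series.mean


def solution_entropy(system: SystemResult) -> float:
    """Total entropy of a box in J K⁻¹ mol⁻¹.

    Solution boxes sum the solute slots plus mean-N_c shell-solvent
    per-molecule slots; pure liquids keep the same N_c count of bulk
    molecules.  A missing component is an explicit error naming the slot.
    """
    kind = system.solvent_kind
    if kind not in SOLVENT_SLOTS:
        raise ValueError(f"unknown solvent kind '{kind}'")
    total = 0.0
    if system.is_solution:
        for slot in SOLUTE_SLOTS:
            if slot not in system.solute_terms:
                raise KeyError(
                    f"system '{system.label}': missing solute entropy "
                    f"component '{slot}'")
            total += system.solute_terms[slot]
    per_solvent = 0.0
    for slot in SOLVENT_SLOTS[kind]:
        if slot not in system.solvent_terms:
            raise KeyError(
                f"system '{system.label}': missing {kind} entropy "
                f"component '{slot}'")
        per_solvent += system.solvent_terms[slot]
    return total + system.mean_nc * per_solvent


@dataclass
class TransferSummary:
    """ΔH, TΔS, ΔG (kcal/mol) and logP for one water→octanol transfer."""

    delta_h: float
    t_delta_s: float
    delta_g: float
    log_p: float
    temperature: float
    sem: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert abs(self.delta_g - (self.delta_h - self.t_delta_s)) < 1e-10


def logp_from_delta_g(delta_g: float, temperature: float = 298.0) -> float:
    """Eq. logP = −ΔG_transfer / (ln 10 · k_B T), ΔG in kcal/mol."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return -delta_g / (math.log(10.0) * KB_KCAL * temperature)


def transfer(x_oct: SystemResult, wat: SystemResult,
             oct_: SystemResult, x_aq: SystemResult) -> TransferSummary:
    """Water→octanol transfer from the four independent boxes.

    The pure-liquid boxes inherit the paired solution's mean N_c so the
    solvent stoichiometry balances on both sides of the transfer.
    """
    systems = (x_oct, wat, oct_, x_aq)
    temps = [s.temperature for s in systems]
    if max(temps) - min(temps) > 0.5:
        raise ValueError(f"temperature mismatch across systems: {temps}")
    t = float(np.mean(temps))
    wat.mean_nc = x_aq.mean_nc
    oct_.mean_nc = x_oct.mean_nc
    delta_h = (x_oct.enthalpy + wat.enthalpy) - (oct_.enthalpy + x_aq.enthalpy)
    s = {sys_.label: solution_entropy(sys_) * J_TO_KCAL for sys_ in systems}
    delta_s = (s[x_oct.label] + s[wat.label]) - (s[oct_.label] + s[x_aq.label])
    t_delta_s = t * delta_s
    delta_g = delta_h - t_delta_s
    return TransferSummary(delta_h=delta_h, t_delta_s=t_delta_s,
                           delta_g=delta_g,
                           log_p=logp_from_delta_g(delta_g, t),
                           temperature=t)


def performance_metrics(predicted, experimental) -> tuple[float, float]:
    """(MAE, RMSE) of predicted vs experimental values."""
    pred = np.asarray(predicted, dtype=float)
    expt = np.asarray(experimental, dtype=float)
    if pred.shape != expt.shape or pred.size < 1:
        raise ValueError(
            f"predicted ({pred.size}) and experimental ({expt.size}) lists "
            f"must have equal nonzero length")
    delta = pred - expt
    return float(np.mean(np.abs(delta))), float(np.sqrt(np.mean(delta**2)))


def replicate_sem(values) -> float:
    """Standard error of the mean over replicate simulations: s/√n."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("SEM requires at least two replicates")
    return float(np.std(v, ddof=1) / math.sqrt(v.size))


def load_reference_table() -> pd.DataFrame:
    """Reference water→octanol transfer results for the 22 SAMPL7
    N-acyl sulfonamide bioisosteric solutes (SM25–SM46).

    Columns: solute, delta_h, t_delta_s, delta_g (kcal/mol), logp_calc,
    sem (logP units), logp_exp, abs_dlogp.
    """
    with resources.files("eemcc.data").joinpath(
            "sampl7_reference.csv").open() as fh:
        return pd.read_csv(fh)
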
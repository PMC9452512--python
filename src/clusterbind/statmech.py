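"""Statistical-mechanical occupancy models for binding-site clusters.

A cluster with ``n`` specific sites has microstates sigma = subsets of bound
sites.  Each state carries the Boltzmann weight

    w(sigma) = prod_{i in sigma} (c / K_d,i) * exp(-eps_clash * n_clash(sigma))

where ``c`` is the free transcription-factor concentration, ``K_d,i`` the
per-site dissociation constant and ``n_clash(sigma)`` the number of bound
pairs whose sites share at least one basepair.  The weight convention makes
the single-site occupancy exactly the Langmuir isotherm c / (K_d + c).

Three model modes:

``independent``
    Overlaps ignored (eps_clash treated as 0); the mean occupancy is the
    independent-site sum  <N> = sum_i c / (c + K_d,i).
``exclusive``
    Full steric occlusion: states containing a clashing pair are forbidden
    (the allowed states are the independent sets of the overlap graph).
``permissive``
    All 2^n states allowed; each clashing bound pair pays a repulsive
    penalty eps_clash (in k_B T).  eps_clash = 0 reduces to independent,
    eps_clash -> infinity reduces to exclusive.

Energies and dissociation constants are interchangeable through
``eps_bs = ln(K_d / c_ref)`` for a chosen reference concentration.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .designs import ClusterDesign, shared_basepairs

__all__ = [
    "MODES",
    "MAX_ENUMERATED_SITES",
    "BindingConfiguration",
    "StatMechModel",
    "OccupancyCurve",
    "EnumerationSizeError",
    "enumerate_states",
    "state_weight",
    "partition_function",
    "mean_occupancy",
    "state_probabilities",
    "occupancy_curve",
    "kd_to_energy",
    "energy_to_kd",
]

MODES = ("independent", "exclusive", "permissive")

#: Enumeration is 2^n; refuse designs beyond this many specific sites.
MAX_ENUMERATED_SITES = 16


class EnumerationSizeError(ValueError):
    """Design has more specific sites than the enumeration cap allows."""


@dataclass(frozen=True)
class BindingConfiguration:
    """One microstate: the subset of bound sites (indices into the
    specific-site list), its occupancy count and its clashing-pair count."""

    bound: tuple[int, ...]
    clash_pairs: int = 0

    @property
    def n_bound(self) -> int:
        return len(self.bound)


@dataclass
class StatMechModel:
    """Parameterization of the occupancy model for one cluster.

    Parameters
    ----------
    kds : sequence of float
        Per-specific-site dissociation constants, nM, in site (start) order.
    mode : {"independent", "exclusive", "permissive"}
    eps_clash : float
        Clash penalty in k_B T; used by the permissive mode only.  Must be
        >= 0 (repulsive).
    c_ref : float
        Reference concentration (nM) for the energy convention
        eps_bs = ln(K_d / c_ref).
    """

    kds: np.ndarray
    mode: str = "independent"
    eps_clash: float = 0.0
    c_ref: float = 1.0

    def __post_init__(self) -> None:
        self.kds = np.asarray(self.kds, dtype=float)
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if np.any(self.kds <= 0):
            raise ValueError("all K_d must be > 0")
        if self.eps_clash < 0:
            raise ValueError("eps_clash must be >= 0 (repulsive penalty)")
        if not self.c_ref > 0:
            raise ValueError("c_ref must be > 0")

    @classmethod
    def from_design(
        cls,
        design: ClusterDesign,
        consensus_kd: float,
        mode: str = "independent",
        eps_clash: float = 0.0,
        c_ref: float = 1.0,
    ) -> "StatMechModel":
        return cls(
            kds=np.asarray(design.site_kds(consensus_kd)),
            mode=mode,
            eps_clash=eps_clash,
            c_ref=c_ref,
        )

    @property
    def binding_energies(self) -> np.ndarray:
        """Per-site eps_bs in k_B T under the c_ref convention."""
        return kd_to_energy(self.kds, self.c_ref)


@dataclass
class OccupancyCurve:
    """Mean occupancy <N>(c) on a concentration grid, plus the saturation
    limit <N>_max (c -> infinity)."""

    concentrations: np.ndarray
    mean_occupancy: np.ndarray
    n_max: float
    target_id: str = ""
    mode: str = "independent"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target_id": self.target_id,
                "mode": self.mode,
                "c_nM": self.concentrations,
                "N_mean": self.mean_occupancy,
            }
        )

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.concentrations, self.mean_occupancy, **kwargs)
        ax.set_xscale("log")
        ax.set_xlabel("free TF concentration (nM)")
        ax.set_ylabel(r"mean occupancy $\langle N\rangle$")
        return ax


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def _clash_pair_indices(design: ClusterDesign) -> list[tuple[int, int]]:
    sites = design.specific_sites()
    return [
        (i, j)
        for i in range(len(sites))
        for j in range(i + 1, len(sites))
        if shared_basepairs(sites[i], sites[j]) >= 1
    ]


def _count_clashes(bound: tuple[int, ...], pairs: Sequence[tuple[int, int]]) -> int:
    s = set(bound)
    return sum(1 for i, j in pairs if i in s and j in s)


def enumerate_states(
    design: ClusterDesign,
    mode: str = "independent",
    max_sites: int = MAX_ENUMERATED_SITES,
) -> list[BindingConfiguration]:
    """All microstates of a cluster under the given model mode.

    Permissive/independent modes list all 2^n subsets of specific sites;
    the exclusive mode keeps only subsets with no clashing pair (independent
    sets of the overlap graph).  The empty configuration is always present.
    NS-class sites carry no statistical weight and are excluded.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    n = design.n_sites
    if n > max_sites:
        raise EnumerationSizeError(
            f"target {design.target_id}: {n} sites exceeds the enumeration "
            f"cap of {max_sites} (2^n states)"
        )
    pairs = _clash_pair_indices(design)
    states = []
    for size in range(n + 1):
        for combo in itertools.combinations(range(n), size):
            clashes = _count_clashes(combo, pairs)
            if mode == "exclusive" and clashes > 0:
                continue
            states.append(BindingConfiguration(bound=combo, clash_pairs=clashes))
    return states


def state_weight(
    config: BindingConfiguration, c: float, model: StatMechModel
) -> float:
    """Boltzmann weight of one configuration at free concentration ``c``."""
    if c < 0:
        raise ValueError("concentration must be >= 0")
    w = 1.0
    for i in config.bound:
        w *= c / model.kds[i]
    if model.mode == "permissive":
        w *= math.exp(-model.eps_clash * config.clash_pairs)
    return w


def _weights_matrix(
    states: Sequence[BindingConfiguration],
    model: StatMechModel,
    conc: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(n_states, n_conc) weight matrix and the per-state occupancy counts."""
    n_bound = np.array([s.n_bound for s in states], dtype=float)
    inv_kd_prod = np.array(
        [np.prod(1.0 / model.kds[list(s.bound)]) for s in states]
    )
    if model.mode == "permissive":
        clash = np.array([s.clash_pairs for s in states], dtype=float)
        inv_kd_prod = inv_kd_prod * np.exp(-model.eps_clash * clash)
    w = inv_kd_prod[:, None] * conc[None, :] ** n_bound[:, None]
    return w, n_bound


def _as_grid(c) -> tuple[np.ndarray, bool]:
    conc = np.atleast_1d(np.asarray(c, dtype=float))
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    return conc, np.isscalar(c) or np.ndim(c) == 0


def partition_function(design: ClusterDesign, c, model: StatMechModel):
    """Partition function Z(c) = sum over states of w(sigma); Z >= 1."""
    conc, scalar = _as_grid(c)
    states = enumerate_states(design, model.mode)
    w, _ = _weights_matrix(states, model, conc)
    z = w.sum(axis=0)
    return float(z[0]) if scalar else z


def mean_occupancy(design: ClusterDesign, c, model: StatMechModel):
    """Mean number of bound TFs per DNA molecule, <N>(c).

    For the independent mode this equals sum_i c / (c + K_d,i) exactly.
    """
    conc, scalar = _as_grid(c)
    if model.mode == "independent":
        n = conc[None, :] / (conc[None, :] + model.kds[:, None])
        out = n.sum(axis=0) if model.kds.size else np.zeros_like(conc)
    else:
        states = enumerate_states(design, model.mode)
        w, n_bound = _weights_matrix(states, model, conc)
        out = (n_bound[:, None] * w).sum(axis=0) / w.sum(axis=0)
    return float(out[0]) if scalar else out


def state_probabilities(
    design: ClusterDesign, c: float, model: StatMechModel
) -> pd.DataFrame:
    """Per-state probabilities P(sigma) = w/Z and occupancy contributions
    N(sigma) P(sigma) at a single concentration."""
    conc, _ = _as_grid(c)
    if conc.size != 1:
        raise ValueError("state_probabilities takes a single concentration")
    states = enumerate_states(design, model.mode)
    w, n_bound = _weights_matrix(states, model, conc)
    p = w[:, 0] / w[:, 0].sum()
    return pd.DataFrame(
        {
            "state_id": ["+".join(map(str, s.bound)) or "empty" for s in states],
            "bound_sites": [s.bound for s in states],
            "n_bound": n_bound.astype(int),
            "clash_pairs": [s.clash_pairs for s in states],
            "P": p,
            "occupancy_contribution": n_bound * p,
        }
    )


def saturation_occupancy(design: ClusterDesign, model: StatMechModel) -> float:
    """<N>_max, the c -> infinity limit of the mean occupancy.

    All sites for independent/permissive (finite eps_clash); the maximum
    independent-set size of the overlap graph for exclusive.
    """
    if model.mode == "exclusive":
        states = enumerate_states(design, "exclusive")
        return float(max(s.n_bound for s in states))
    return float(design.n_sites)


def occupancy_curve(
    design: ClusterDesign, concentrations, model: StatMechModel
) -> OccupancyCurve:
    """Mean-occupancy curve on a strictly increasing, nonnegative grid."""
    conc = np.asarray(concentrations, dtype=float)
    if conc.ndim != 1 or conc.size < 1:
        raise ValueError("concentration grid must be a 1-D array")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentration grid must be strictly increasing")
    if conc[0] < 0:
        raise ValueError("concentrations must be >= 0")
    return OccupancyCurve(
        concentrations=conc,
        mean_occupancy=np.asarray(mean_occupancy(design, conc, model)),
        n_max=saturation_occupancy(design, model),
        target_id=design.target_id,
        mode=model.mode,
    )


def kd_to_energy(kd, c_ref: float = 1.0):
    """Binding energy eps_bs = ln(K_d / c_ref), in k_B T."""
    kd = np.asarray(kd, dtype=float)
    if np.any(kd <= 0) or not c_ref > 0:
        raise ValueError("kd and c_ref must be > 0")
    out = np.log(kd / c_ref)
    return float(out) if out.ndim == 0 else out


def energy_to_kd(eps, c_ref: float = 1.0):
    """Inverse of :func:`kd_to_energy`: K_d = c_ref * exp(eps_bs)."""
    if not c_ref > 0:
        raise ValueError("c_ref must be > 0")
    out = c_ref * np.exp(np.asarray(eps, dtype=float))
    return float(out) if out.ndim == 0 else out
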
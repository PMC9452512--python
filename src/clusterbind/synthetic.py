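"""Seeded synthetic datasets with the statistical structure of the assays.

The study's raw measurements are not bundled here, so this module generates
data with the same shape and noise structure:

* ``simulate_imitomi`` — per-chamber saturation-binding measurements across
  8 concentration sections (log-spaced), tens of replicate chambers per
  section, a fluorescence step per bound TF, lognormal chamber-to-chamber
  DNA-signal variability and Gaussian reading noise.  Ground truth (per-site
  K_ds, clash energy, step) is emitted alongside.
* ``simulate_platereader`` — OD/GFP/mScarlet kinetics at a 10-minute cadence
  under induced/uninduced conditions: logistic growth, GFP accumulation at a
  rate combining a baseline, a site-count-proportional non-specific leak
  (both conditions) and a hinge response to the predicted occupancy at the
  induced nuclear TF concentration (induced only).
* ``fixture_library`` — the cluster-design families the analysis exercises:
  consensus/weak/very-weak multiplicity series, a spacing series, overlap
  series sharing 1 or 3 bp, mixed-affinity clusters and two-region
  native-promoter style replacements.

All randomness flows through one ``numpy`` Generator: a fixed seed gives
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .designs import BindingSite, ClusterDesign
from .invivo import predict_occupancy
from .statmech import StatMechModel, mean_occupancy

__all__ = [
    "SCHEMA_VERSION",
    "PlateReaderConfig",
    "SimulationConfig",
    "simulate_imitomi",
    "simulate_platereader",
    "normalized_bound",
    "fixture_library",
    "default_concentration_sections",
]

SCHEMA_VERSION = "1"


def default_concentration_sections(
    n_sections: int = 8, c_min: float = 1.0, c_max: float = 1e4
) -> np.ndarray:
    """Log-spaced free-TF concentrations (nM), one per chip section."""
    return np.geomspace(c_min, c_max, n_sections)


@dataclass
class PlateReaderConfig:
    """Growth/expression parameters for the platereader generator."""

    od0: float = 0.15
    od_max: float = 1.2
    growth_rate: float = 0.45  # 1/h
    duration_h: float = 20.0
    cadence_min: float = 10.0
    blank_od: float = 0.04
    blank_gfp: float = 50.0
    blank_mscarlet: float = 30.0
    baseline_rate: float = 20.0  # GFP/OD units at the window
    hinge_slope: float = 500.0  # per occupancy above theta
    theta: float = 1.0  # occupancy threshold
    leak_per_site: float = 15.0  # non-specific leak per specific site
    induced_conc_nm: float = 600.0  # nuclear TF concentration when induced
    noise_od: float = 0.004  # additive OD reading noise (sd)
    noise_gfp_frac: float = 0.10  # multiplicative GFP noise (sd fraction)
    mscarlet_rate: float = 300.0  # control channel, same for all strains


@dataclass
class SimulationConfig:
    """Shared configuration for the synthetic generators.

    Defaults mirror the assay geometry: 8 concentration sections, 30
    chambers per section (within the 20-84 per-sample range), Gaussian
    bound-signal noise at 5 % of the single-site saturation fluorescence,
    a 500 RFU step per bound TF and a consensus K_d of 10 nM.
    """

    seed: int = 0
    designs: list[ClusterDesign] = field(default_factory=list)
    consensus_kd: float = 10.0  # nM
    concentrations: np.ndarray = field(
        default_factory=default_concentration_sections
    )
    chambers_per_section: int = 30
    noise_sd: float = 0.05  # fraction of step_rfu
    step_rfu: float = 500.0  # RFU per bound TF
    dna_ref: float = 1000.0  # reference DNA signal, RFU
    dna_cv: float = 0.10  # lognormal sd of chamber DNA variability
    n_experiments: int = 3
    #: per-target mode override; default independent, or permissive with
    #: eps_clash for overlapping designs
    modes: dict = field(default_factory=dict)
    eps_clash: float = 2.0  # used for overlapping designs unless overridden
    platereader: PlateReaderConfig = field(default_factory=PlateReaderConfig)

    def model_for(self, design: ClusterDesign) -> StatMechModel:
        mode = self.modes.get(
            design.target_id,
            "permissive" if design.has_overlaps() else "independent",
        )
        return StatMechModel.from_design(
            design,
            self.consensus_kd,
            mode=mode,
            eps_clash=self.eps_clash if mode == "permissive" else 0.0,
        )

    def validate(self) -> None:
        if self.chambers_per_section < 1:
            raise ValueError("chambers_per_section must be >= 1")
        if self.noise_sd < 0 or self.dna_cv < 0:
            raise ValueError("noise parameters must be >= 0")
        if not (self.step_rfu > 0 and self.dna_ref > 0 and self.consensus_kd > 0):
            raise ValueError("step_rfu, dna_ref and consensus_kd must be > 0")
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.ndim != 1 or np.any(conc < 0):
            raise ValueError("concentrations must be a 1-D nonnegative grid")


def simulate_imitomi(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-chamber saturation-binding measurements plus ground truth.

    Bound signal per chamber:

        bound = step_rfu * <N>_true(c) * (dna / dna_ref) + Normal(0, noise)

    with ``dna`` drawn lognormally around ``dna_ref`` and ``noise`` the
    configured fraction of ``step_rfu`` (the single-site B_max).  Free
    concentrations are treated as known exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    conc = np.asarray(config.concentrations, dtype=float)
    rows = []
    truth_rows = []
    sigma = config.noise_sd * config.step_rfu
    log_sd = np.sqrt(np.log(1.0 + config.dna_cv**2))
    for design in config.designs:
        model = config.model_for(design)
        if design.n_sites:
            occ = np.asarray(mean_occupancy(design, conc, model))
        else:
            occ = np.zeros_like(conc)
        truth_rows.append(
            {
                "target_id": design.target_id,
                "n_sites": design.n_sites,
                "mode": model.mode,
                "kds_nM": ";".join(f"{k:g}" for k in model.kds),
                "eps_clash": model.eps_clash,
                "step_rfu": config.step_rfu,
                "dna_ref": config.dna_ref,
                "noise_sd": config.noise_sd,
                "schema_version": SCHEMA_VERSION,
            }
        )
        for sec, c in enumerate(conc):
            dna = config.dna_ref * np.exp(
                log_sd * (rng.standard_normal(config.chambers_per_section))
                - 0.5 * log_sd**2
            )
            noise = sigma * rng.standard_normal(config.chambers_per_section)
            bound = config.step_rfu * occ[sec] * dna / config.dna_ref + noise
            for rep in range(config.chambers_per_section):
                rows.append(
                    {
                        "chamber_id": f"{design.target_id}_s{sec}_r{rep}",
                        "target_id": design.target_id,
                        "free_conc_nM": c,
                        "bound_rfu": bound[rep],
                        "dna_rfu": dna[rep],
                        "experiment_id": f"exp{rep % config.n_experiments}",
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def normalized_bound(measurements: pd.DataFrame, dna_ref: float) -> pd.Series:
    """Bound signal corrected for chamber DNA variability:
    bound * dna_ref / dna."""
    return measurements["bound_rfu"] * dna_ref / measurements["dna_rfu"]


def _logistic_od(t: np.ndarray, od0: float, od_max: float, r: float) -> np.ndarray:
    e = np.exp(r * t)
    return od_max * od0 * e / (od_max + od0 * (e - 1.0))


def _logistic_od_integral(
    t: np.ndarray, od0: float, od_max: float, r: float
) -> np.ndarray:
    return (od_max / r) * np.log(1.0 + od0 * (np.exp(r * t) - 1.0) / od_max)


def simulate_platereader(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Platereader OD/GFP/mScarlet time series plus ground truth.

    GFP accumulates as dG/dt = rate * OD(t), with rate the baseline plus a
    site-count-proportional leak (both conditions) plus, when induced, the
    hinge response to the strain's predicted occupancy at the induced
    nuclear concentration.  Blank offsets and reading noise are added to
    every channel.
    """
    config.validate()
    pr = config.platereader
    rng = np.random.default_rng(config.seed + 1)
    n_points = int(pr.duration_h * 60.0 / pr.cadence_min) + 1
    t = np.arange(n_points) * pr.cadence_min / 60.0
    od = _logistic_od(t, pr.od0, pr.od_max, pr.growth_rate)
    od_int = _logistic_od_integral(t, pr.od0, pr.od_max, pr.growth_rate)
    # scale so that a unit rate contributes ~1 GFP/OD inside the window
    shape = np.where(od > 0, od_int / np.maximum(od, 1e-12), 0.0)
    mid = (t >= 8.5) & (t <= 9.5)
    shape_norm = shape / shape[mid].mean()

    rows = []
    truth_rows = []
    for design in config.designs:
        occ = predict_occupancy(
            design,
            pr.induced_conc_nm,
            config.consensus_kd,
            eps_clash=config.eps_clash,
        )
        hinge = pr.hinge_slope * max(0.0, occ - pr.theta)
        leak = pr.leak_per_site * design.n_sites
        truth_rows.append(
            {
                "strain_id": design.target_id,
                "n_sites": design.n_sites,
                "occupancy_induced": occ,
                "theta": pr.theta,
                "hinge_slope": pr.hinge_slope,
                "baseline_rate": pr.baseline_rate,
                "leak_per_site": pr.leak_per_site,
                "induced_conc_nM": pr.induced_conc_nm,
                "schema_version": SCHEMA_VERSION,
            }
        )
        for condition in ("uninduced", "induced"):
            rate = pr.baseline_rate + leak + (hinge if condition == "induced" else 0.0)
            gfp_true = rate * shape_norm * od
            ms_true = pr.mscarlet_rate * shape_norm * od
            od_read = od + pr.blank_od + pr.noise_od * rng.standard_normal(n_points)
            gfp_read = (
                gfp_true * (1.0 + pr.noise_gfp_frac * rng.standard_normal(n_points))
                + pr.blank_gfp
            )
            ms_read = (
                ms_true * (1.0 + pr.noise_gfp_frac * rng.standard_normal(n_points))
                + pr.blank_mscarlet
            )
            for i in range(n_points):
                rows.append(
                    {
                        "strain_id": design.target_id,
                        "condition": condition,
                        "time_h": t[i],
                        "od600": od_read[i],
                        "gfp": gfp_read[i],
                        "mscarlet": ms_read[i],
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Fixture design library
# ---------------------------------------------------------------------------

def _cluster(
    target_id: str,
    classes: Sequence[str],
    motif_length: int = 9,
    gap: int = 5,
    start: int = 0,
    target_length: int = 90,
) -> ClusterDesign:
    """Evenly spaced cluster with the given per-site affinity classes."""
    sites = [
        BindingSite(
            site_id=f"{target_id}.{i}",
            start=start + i * (motif_length + gap),
            length=motif_length,
            affinity_class=cls,
        )
        for i, cls in enumerate(classes)
    ]
    return ClusterDesign(target_id=target_id, sites=sites, target_length=target_length)


def _overlap_cluster(
    target_id: str,
    n_sites: int,
    shared_bp: int,
    affinity_class: str,
    motif_length: int = 9,
) -> ClusterDesign:
    """Chain of sites where each neighbor pair shares ``shared_bp`` bp."""
    stride = motif_length - shared_bp
    sites = [
        BindingSite(
            site_id=f"{target_id}.{i}",
            start=i * stride,
            length=motif_length,
            affinity_class=affinity_class,
        )
        for i in range(n_sites)
    ]
    return ClusterDesign(target_id=target_id, sites=sites)


def _pho5_like(
    target_id: str, nfr: str, nor: str, motif_length: int = 6
) -> ClusterDesign:
    """Two-region promoter: each region native (N: one strong site),
    ablated (A: no site) or a cluster of 5 weak sites (C)."""
    sites: list[BindingSite] = []

    def region(tag: str, kind: str, anchor: int) -> None:
        if kind == "A":
            return
        if kind == "N":
            sites.append(
                BindingSite(
                    site_id=f"{target_id}.{tag}",
                    start=anchor,
                    length=motif_length,
                    affinity_class="S",
                )
            )
        elif kind == "C":
            for i in range(5):
                sites.append(
                    BindingSite(
                        site_id=f"{target_id}.{tag}{i}",
                        start=anchor + i * (motif_length + 2),
                        length=motif_length,
                        affinity_class="W",
                    )
                )
        else:
            raise ValueError(f"unknown region kind {kind!r}")

    region("nfr", nfr, 5)
    region("nor", nor, 50)
    return ClusterDesign(target_id=target_id, sites=sites)


def fixture_library(motif_length: int = 9) -> list[ClusterDesign]:
    """The standard design families used throughout the analysis.

    Multiplicity series S1/S3/S6 and W1-W6; very-weak V-3/V-6 and W-6;
    mixed-affinity W3V-3 plus its reordering; a two-site spacing series
    with gaps 0-20 bp; overlap chains of 2-4 strong or weak sites sharing
    1 or 3 bp; native-promoter style two-region N/A/C replacements; and a
    no-site NS control target.
    """
    designs: list[ClusterDesign] = []
    designs.append(ClusterDesign(target_id="NS", sites=[]))
    for n in (1, 3, 6):
        designs.append(_cluster(f"S{n}", ["S"] * n, motif_length))
    for n in range(1, 7):
        designs.append(_cluster(f"W{n}", ["W"] * n, motif_length))
    for n in (3, 6):
        designs.append(_cluster(f"V-{n}", ["V-"] * n, motif_length))
    designs.append(_cluster("W-6", ["W-"] * 6, motif_length))
    designs.append(_cluster("W3V-3", ["W"] * 3 + ["V-"] * 3, motif_length))
    designs.append(_cluster("V-3W3", ["V-"] * 3 + ["W"] * 3, motif_length))
    for delta in range(0, 21):
        designs.append(
            ClusterDesign(
                target_id=f"SPW_d{delta}",
                sites=[
                    BindingSite(f"SPW_d{delta}.0", 0, motif_length, "W"),
                    BindingSite(
                        f"SPW_d{delta}.1", motif_length + delta, motif_length, "W"
                    ),
                ],
            )
        )
    for cls in ("S", "W"):
        for shared in (1, 3):
            for n in (2, 3, 4):
                designs.append(
                    _overlap_cluster(
                        f"OV{shared}_{cls}{n}", n, shared, cls, motif_length
                    )
                )
    for nfr in ("N", "A", "C"):
        for nor in ("N", "A", "C"):
            designs.append(_pho5_like(f"PHO5_{nfr}-{nor}", nfr, nor))
    return designs
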
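"""Binding-site cluster designs.

A *cluster design* is a short DNA target (90 bp by default, mirroring the
immobilized double-stranded targets used in microfluidic binding assays)
carrying one or more positioned binding sites for a single transcription
factor.  Sites are annotated with an affinity class relative to the consensus
motif: S (consensus/strong, 1x), W (10x weaker), W- (20x), V (50x), V- (100x)
and NS (non-specific, no specific binding).  All geometry — overlaps, shared
basepairs and inter-site spacing — is derived from 0-based, half-open
coordinate intervals, which keeps shared-basepair arithmetic exact.

Sites are modeled strand-agnostically: downstream occupancy models depend
only on the intervals and the per-site dissociation constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AFFINITY_MULTIPLIERS",
    "NONSPECIFIC",
    "DEFAULT_MOTIF_LENGTH",
    "DEFAULT_TARGET_LENGTH",
    "BindingSite",
    "ClusterDesign",
    "DesignError",
    "DesignIOError",
    "shared_basepairs",
    "overlap_fraction",
    "spacing",
    "kd_for_class",
    "read_designs",
    "write_designs",
    "emit_fasta",
]

#: Fold-weaker dissociation constant multipliers per affinity class,
#: relative to the consensus site.
AFFINITY_MULTIPLIERS: dict[str, float] = {
    "S": 1.0,
    "W": 10.0,
    "W-": 20.0,
    "V": 50.0,
    "V-": 100.0,
}

#: Class label for sites with no specific binding (excluded from occupancy
#: models; carries no dissociation constant).
NONSPECIFIC = "NS"

DEFAULT_MOTIF_LENGTH = 9  # bp, Zif268-like zinc-finger motif
DEFAULT_TARGET_LENGTH = 90  # bp

#: Neutral backbone filler for emitted FASTA where no site is placed.  A
#: fixed, documented constant (repeated as needed); deliberately devoid of
#: the placeholder motifs below.
BACKBONE_UNIT = "TTAGCTCATAGTACTCCTAA"

#: Placeholder motifs written into site intervals when emitting FASTA.
_MOTIF_PLACEHOLDERS = {9: "GCGTGGGCG", 6: "CACGTG"}


class DesignError(ValueError):
    """Invalid binding-site or cluster-design geometry/parameters."""


class DesignIOError(DesignError):
    """Malformed design file; message carries the offending row."""


@dataclass(frozen=True)
class BindingSite:
    """One positioned binding site on a target.

    Parameters
    ----------
    site_id : str
        Unique (within a target) identifier.
    start : int
        0-based offset of the first basepair of the motif on the target.
    length : int
        Motif length in bp (default 9, Zif268-like).
    affinity_class : str
        One of ``S, W, W-, V, V-, NS``.
    kd : float or None
        Dissociation constant in nM.  ``None`` means "derive from the
        affinity class and a consensus K_d" via :func:`kd_for_class`.
    """

    site_id: str
    start: int
    length: int = DEFAULT_MOTIF_LENGTH
    affinity_class: str = "S"
    kd: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise DesignError(f"site {self.site_id}: start must be >= 0")
        if self.length < 1:
            raise DesignError(f"site {self.site_id}: length must be >= 1")
        if (
            self.affinity_class != NONSPECIFIC
            and self.affinity_class not in AFFINITY_MULTIPLIERS
        ):
            raise DesignError(
                f"site {self.site_id}: unknown affinity class "
                f"{self.affinity_class!r}"
            )
        if self.kd is not None and not self.kd > 0:
            raise DesignError(f"site {self.site_id}: kd must be > 0 (nM)")

    @property
    def end(self) -> int:
        """One-past-the-last basepair (half-open interval end)."""
        return self.start + self.length

    @property
    def is_specific(self) -> bool:
        return self.affinity_class != NONSPECIFIC

    def resolved_kd(self, consensus_kd: float) -> float:
        """K_d in nM: explicit value if set, else class multiplier x consensus."""
        if not self.is_specific:
            raise DesignError(
                f"site {self.site_id}: NS sites have no dissociation constant"
            )
        if self.kd is not None:
            return self.kd
        return kd_for_class(self.affinity_class, consensus_kd)


@dataclass
class ClusterDesign:
    """A DNA target with an ordered list of binding sites."""

    target_id: str
    sites: list[BindingSite] = field(default_factory=list)
    target_length: int = DEFAULT_TARGET_LENGTH

    def __post_init__(self) -> None:
        self.sites = sorted(self.sites, key=lambda s: (s.start, s.site_id))
        seen: set[str] = set()
        for s in self.sites:
            if s.site_id in seen:
                raise DesignError(
                    f"target {self.target_id}: duplicate site_id {s.site_id!r}"
                )
            seen.add(s.site_id)
            if s.end > self.target_length:
                raise DesignError(
                    f"target {self.target_id}: site {s.site_id} "
                    f"[{s.start}, {s.end}) exceeds target length "
                    f"{self.target_length}"
                )

    @property
    def n_sites(self) -> int:
        """Number of specific (non-NS) sites."""
        return len(self.specific_sites())

    def specific_sites(self) -> list[BindingSite]:
        return [s for s in self.sites if s.is_specific]

    def site_kds(self, consensus_kd: float) -> list[float]:
        """Per-specific-site K_d (nM), in start order."""
        return [s.resolved_kd(consensus_kd) for s in self.specific_sites()]

    def overlap_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (into ``specific_sites()``) sharing >= 1 bp."""
        sites = self.specific_sites()
        return [
            (i, j)
            for i in range(len(sites))
            for j in range(i + 1, len(sites))
            if shared_basepairs(sites[i], sites[j]) >= 1
        ]

    def has_overlaps(self) -> bool:
        return bool(self.overlap_pairs())


def shared_basepairs(a: BindingSite, b: BindingSite) -> int:
    """Number of basepairs shared by two sites (0 when disjoint).

    The intersection length of the half-open intervals ``[start, end)``;
    symmetric in its arguments.
    """
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlap_fraction(shared: int, motif_length: int) -> int:
    """Shared basepairs as an integer percent of the motif length.

    E.g. 3 of 9 bp -> 33 %, 1 of 9 bp -> 11 %.
    """
    if motif_length <= 0:
        raise DesignError("motif_length must be > 0")
    if not 0 <= shared <= motif_length:
        raise DesignError("shared basepairs must lie in [0, motif_length]")
    return round(100.0 * shared / motif_length)


def spacing(a: BindingSite, b: BindingSite) -> int:
    """Gap in bp between site ``a`` and the following site ``b``.

    Negative for overlapping sites, in which case ``-spacing`` equals the
    number of shared basepairs; 0 for abutting sites.
    """
    if a.start > b.start:
        raise DesignError("spacing: site a must precede site b")
    return b.start - a.end


def kd_for_class(label: str, consensus_kd: float) -> float:
    """K_d (nM) for an affinity class given the consensus K_d."""
    if label == NONSPECIFIC:
        raise DesignError("NS class: no specific binding, no K_d defined")
    try:
        mult = AFFINITY_MULTIPLIERS[label]
    except KeyError:
        raise DesignError(f"unknown affinity class {label!r}") from None
    if not consensus_kd > 0:
        raise DesignError("consensus_kd must be > 0")
    return consensus_kd * mult


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["target_id", "site_id", "start", "length", "class", "kd_nM"]


def _designs_to_frame(designs: Iterable[ClusterDesign]) -> pd.DataFrame:
    rows = []
    for d in designs:
        if not d.sites:
            rows.append(
                {
                    "target_id": d.target_id,
                    "site_id": "",
                    "start": pd.NA,
                    "length": pd.NA,
                    "class": "",
                    "kd_nM": pd.NA,
                    "target_length": d.target_length,
                }
            )
        for s in d.sites:
            rows.append(
                {
                    "target_id": d.target_id,
                    "site_id": s.site_id,
                    "start": s.start,
                    "length": s.length,
                    "class": s.affinity_class,
                    "kd_nM": s.kd if s.kd is not None else pd.NA,
                    "target_length": d.target_length,
                }
            )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS + ["target_length"])


def write_designs(designs: Sequence[ClusterDesign], path: str | Path) -> None:
    """Write designs as CSV (one row per site) or JSON, chosen by suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = [
            {
                "target_id": d.target_id,
                "target_length": d.target_length,
                "sites": [
                    {
                        "site_id": s.site_id,
                        "start": s.start,
                        "length": s.length,
                        "class": s.affinity_class,
                        "kd_nM": s.kd,
                    }
                    for s in d.sites
                ],
            }
            for d in designs
        ]
        path.write_text(json.dumps(payload, indent=1))
    else:
        _designs_to_frame(designs).to_csv(path, index=False)


def read_designs(path: str | Path) -> list[ClusterDesign]:
    """Read a design table (CSV with one row per site, or JSON mirror).

    Malformed rows are reported with their row number.  An empty table
    yields an empty list.  Site lists come back sorted by start.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        designs = []
        for entry in payload:
            sites = [
                BindingSite(
                    site_id=s["site_id"],
                    start=int(s["start"]),
                    length=int(s["length"]),
                    affinity_class=s["class"],
                    kd=None if s.get("kd_nM") is None else float(s["kd_nM"]),
                )
                for s in entry.get("sites", [])
            ]
            designs.append(
                ClusterDesign(
                    target_id=entry["target_id"],
                    sites=sites,
                    target_length=int(entry.get("target_length", DEFAULT_TARGET_LENGTH)),
                )
            )
        return designs

    df = pd.read_csv(path)
    if df.empty:
        return []
    missing = [c for c in _CSV_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise DesignIOError(f"{path}: missing columns {missing}")
    by_target: dict[str, list[BindingSite]] = {}
    lengths: dict[str, int] = {}
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # 1-based, counting the header line
        tid = str(row["target_id"])
        tlen = row.get("target_length", DEFAULT_TARGET_LENGTH)
        lengths[tid] = (
            DEFAULT_TARGET_LENGTH if pd.isna(tlen) else int(tlen)
        )
        by_target.setdefault(tid, [])
        sid = row.get("site_id")
        if pd.isna(row["start"]) and (pd.isna(sid) or str(sid) == ""):
            continue  # siteless-target marker row
        try:
            kd = row.get("kd_nM")
            site = BindingSite(
                site_id=str(row["site_id"]),
                start=int(row["start"]),
                length=int(row["length"]),
                affinity_class=str(row["class"]),
                kd=None if pd.isna(kd) else float(kd),
            )
        except (DesignError, ValueError, TypeError) as exc:
            raise DesignIOError(f"{path} row {rowno}: {exc}") from exc
        by_target[tid].append(site)
    designs = []
    for tid, sites in by_target.items():
        try:
            designs.append(
                ClusterDesign(target_id=tid, sites=sites, target_length=lengths[tid])
            )
        except DesignError as exc:
            raise DesignIOError(f"{path} target {tid}: {exc}") from exc
    return designs


def _placeholder_motif(length: int) -> str:
    motif = _MOTIF_PLACEHOLDERS.get(length)
    return motif if motif is not None else "N" * length


def target_sequence(design: ClusterDesign) -> str:
    """Backbone-filled target sequence with placeholder motifs at sites.

    Later (rightmost) sites overwrite overlapping earlier ones, so overlap
    geometry remains visible in the emitted sequence.
    """
    n_units = design.target_length // len(BACKBONE_UNIT) + 1
    seq = list((BACKBONE_UNIT * n_units)[: design.target_length])
    for s in design.sites:
        if not s.is_specific:
            continue
        seq[s.start : s.end] = _placeholder_motif(s.length)
    return "".join(seq)


def emit_fasta(designs: Sequence[ClusterDesign], path: str | Path) -> None:
    """Write one FASTA record per design (placeholder backbone + motifs)."""
    records = [
        SeqRecord(
            Seq(target_sequence(d)),
            id=d.target_id,
            description=f"n_sites={d.n_sites} length={d.target_length}",
        )
        for d in designs
    ]
    SeqIO.write(records, str(Path(path)), "fasta")
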
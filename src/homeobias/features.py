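"""Protein-level family identification and physicochemical features.

Family membership is decided by scanning each protein with an ungapped
position-specific scoring matrix (PSSM) for the conserved N-terminal
NAC (NAM/ATAF/CUC) DNA-binding domain, thresholded in bits.  The module
also computes the classic desk characteristics of a transcription-factor
catalogue: length, average molecular weight, isoelectric point (bisection
on the Henderson-Hasselbalch net-charge curve) and putative transmembrane
segments (Kyte-Doolittle hydropathy windows), which flag membrane-bound
family members.

All lookup tables (residue masses, pK set, hydropathy index) ship as
editable TSV files under ``homeobias/data`` and can be swapped by the
user.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Consensus of the bundled NAC-domain profile.  Planted verbatim in the
#: synthetic generator's family members, so recovery on synthetic data
#: is exact by construction.
NAC_DOMAIN_CONSENSUS = "LPPGFRFHPTDEELVVHYLKRKAASAPLPVAIIAEVDLYKFDPWELPAKA"


def _data_path(name: str) -> Path:
    return Path(str(resources.files("homeobias.data").joinpath(name)))


def _read_table(name: str) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(_data_path(name)) as fh:
        header_seen = False
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            key, val = line.split("\t")[:2]
            out[key] = float(val)
    return out


def load_residue_masses() -> dict[str, float]:
    """Average residue masses in Da (amino acid minus one water)."""
    return _read_table("residue_masses.tsv")


def load_kd_scores() -> dict[str, float]:
    """Kyte-Doolittle hydropathy index per residue."""
    return _read_table("kyte_doolittle.tsv")


def load_pk_values() -> list[tuple[str, float, int]]:
    """EMBOSS-style pK table as (group, pK, sign) tuples."""
    rows: list[tuple[str, float, int]] = []
    with open(_data_path("pk_values.tsv")) as fh:
        header_seen = False
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            group, pk, sign = line.split("\t")
            rows.append((group, float(pk), int(sign)))
    return rows


WATER_MASS = 18.02


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier plus uppercase amino-acid sequence.

    ``X`` is tolerated as an unknown residue; every other letter must be
    one of the 20 standard amino acids.
    """

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein id must be nonempty")
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in _AA_INDEX and aa != "X":
                raise ValueError(
                    f"{self.id}: illegal residue {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DomainProfile:
    """Ungapped log-odds profile (bits) over the 20 amino acids.

    ``matrix`` has shape (length, 20), column order :data:`AMINO_ACIDS`.
    A window scores the sum of its per-position log-odds; windows at or
    above ``threshold`` are reported as domain hits.  ``X`` contributes 0.
    """

    matrix: np.ndarray
    threshold: float = 15.0
    background: np.ndarray = field(
        default_factory=lambda: np.full(20, 0.05)
    )

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError("profile matrix must be positions x 20")
        if self.matrix.shape[0] < 1:
            raise ValueError("profile length must be >= 1")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.matrix.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @classmethod
    def from_consensus(
        cls,
        consensus: str,
        match_prob: float = 0.7,
        threshold: float = 15.0,
    ) -> "DomainProfile":
        """Build a profile whose emission puts ``match_prob`` on the
        consensus residue and spreads the rest uniformly, against a
        uniform background."""
        bg = 1.0 / 20.0
        mismatch = (1.0 - match_prob) / 19.0
        mat = np.full((len(consensus), 20), math.log2(mismatch / bg))
        for i, aa in enumerate(consensus):
            mat[i, _AA_INDEX[aa]] = math.log2(match_prob / bg)
        return cls(matrix=mat, threshold=threshold)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#threshold\t{self.threshold}\n")
            fh.write("#background\t" + "\t".join(f"{b:.6g}" for b in self.background) + "\n")
            fh.write("pos\t" + "\t".join(AMINO_ACIDS) + "\n")
            for i, row in enumerate(self.matrix, start=1):
                fh.write(f"{i}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def read(cls, path) -> "DomainProfile":
        threshold = 15.0
        background = np.full(20, 0.05)
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#threshold"):
                    threshold = float(line.split("\t")[1])
                elif line.startswith("#background"):
                    background = np.array([float(x) for x in line.split("\t")[1:]])
                elif line.startswith("pos") or not line.strip():
                    continue
                else:
                    rows.append([float(x) for x in line.split("\t")[1:]])
        return cls(matrix=np.array(rows), threshold=threshold, background=background)


def default_profile() -> DomainProfile:
    """The bundled NAC-domain profile (built from the consensus)."""
    return DomainProfile.from_consensus(NAC_DOMAIN_CONSENSUS)


@dataclass(frozen=True)
class DomainHit:
    """One above-threshold profile window, 1-based inclusive residues."""

    protein_id: str
    start: int
    end: int
    score: float


@dataclass(frozen=True)
class ProteinFeatures:
    id: str
    length: int
    molecular_weight: float
    isoelectric_point: float
    n_domain_hits: int
    tm_segments: tuple[tuple[int, int], ...]

    @property
    def membrane_bound(self) -> bool:
        return len(self.tm_segments) > 0


def scan_domain(protein: ProteinRecord, profile: DomainProfile) -> list[DomainHit]:
    """Score every window of the protein against the profile.

    Returns hits (windows with summed log-odds >= threshold) sorted by
    start coordinate.  Proteins shorter than the profile yield no hits.
    """
    L = profile.length
    n = len(protein.sequence)
    if n < L:
        return []
    # per-(sequence position, profile row) score lookup; X scores 0
    idx = np.array([_AA_INDEX.get(aa, -1) for aa in protein.sequence])
    hits = []
    for s in range(n - L + 1):
        window = idx[s : s + L]
        valid = window >= 0
        score = float(profile.matrix[np.nonzero(valid)[0], window[valid]].sum())
        if score >= profile.threshold:
            hits.append(
                DomainHit(protein_id=protein.id, start=s + 1, end=s + L, score=score)
            )
    return hits


#: Fractional spans of the five classical NAC subdomains (a-e) within a
#: domain hit; the field reports them schematically, so fixed fractions
#: of the hit interval are used.
SUBDOMAIN_FRACTIONS = {
    "a": (0.00, 0.18),
    "b": (0.18, 0.36),
    "c": (0.36, 0.60),
    "d": (0.60, 0.82),
    "e": (0.82, 1.00),
}


def subdomain_intervals(hit: DomainHit) -> dict[str, tuple[int, int]]:
    """Map subdomains a-e to 1-based residue intervals within a hit."""
    span = hit.end - hit.start + 1
    out = {}
    for name, (f0, f1) in SUBDOMAIN_FRACTIONS.items():
        out[name] = (
            hit.start + int(round(f0 * span)),
            hit.start + int(round(f1 * span)) - 1,
        )
    return out


def classify_family(
    proteins: list[ProteinRecord], profile: DomainProfile | None = None
) -> set[str]:
    """Return ids of proteins with at least one domain hit.

    Raises on duplicate protein ids (a catalogue must be unambiguous).
    """
    if profile is None:
        profile = default_profile()
    seen = set()
    for p in proteins:
        if p.id in seen:
            raise ValueError(f"duplicate protein id: {p.id}")
        seen.add(p.id)
    return {p.id for p in proteins if scan_domain(p, profile)}


def molecular_weight(
    protein: ProteinRecord, masses: dict[str, float] | None = None
) -> float:
    """Average molecular weight in Da: residue masses plus one water.

    ``X`` counts as the mean of the 20 standard residue masses.
    """
    if masses is None:
        masses = load_residue_masses()
    x_mass = sum(masses.values()) / len(masses)
    total = WATER_MASS
    for aa in protein.sequence:
        total += x_mass if aa == "X" else masses[aa]
    return total


def net_charge(
    sequence: str, ph: float, pk: list[tuple[str, float, int]] | None = None
) -> float:
    """Henderson-Hasselbalch net charge at a given pH.

    Termini contribute once; ionizable side chains per occurrence.
    ``X`` is ignored.
    """
    if pk is None:
        pk = load_pk_values()
    counts = {}
    for aa in sequence:
        counts[aa] = counts.get(aa, 0) + 1
    charge = 0.0
    for group, pkval, sign in pk:
        if group == "Nterm" or group == "Cterm":
            n = 1
        else:
            n = counts.get(group, 0)
        if n == 0:
            continue
        if sign > 0:
            charge += n / (1.0 + 10.0 ** (ph - pkval))
        else:
            charge -= n / (1.0 + 10.0 ** (pkval - ph))
    return charge


def isoelectric_point(
    protein: ProteinRecord,
    pk: list[tuple[str, float, int]] | None = None,
    tol: float = 1e-4,
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The charge curve is strictly decreasing in pH, so the root is unique.
    """
    if pk is None:
        pk = load_pk_values()
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c = net_charge(protein.sequence, mid, pk)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def find_tm_segments(
    protein: ProteinRecord,
    window: int = 19,
    cutoff: float = 1.6,
    kd: dict[str, float] | None = None,
) -> list[tuple[int, int]]:
    """Putative transmembrane segments by Kyte-Doolittle hydropathy.

    Slides an odd ``window`` over the sequence; maximal runs of windows
    whose mean hydropathy >= ``cutoff`` become segments, reported as the
    1-based residue span covered by the run's windows.  Proteins shorter
    than the window have no segments.
    """
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be odd and >= 5")
    if kd is None:
        kd = load_kd_scores()
    n = len(protein.sequence)
    if n < window:
        return []
    scores = np.array([kd.get(aa, 0.0) for aa in protein.sequence])
    means = np.convolve(scores, np.ones(window) / window, mode="valid")
    above = means >= cutoff
    segments: list[tuple[int, int]] = []
    run_start = None
    for i, flag in enumerate(above):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            segments.append((run_start + 1, i - 1 + window))
            run_start = None
    if run_start is not None:
        segments.append((run_start + 1, len(above) - 1 + window))
    return segments


def compute_features(
    protein: ProteinRecord,
    profile: DomainProfile | None = None,
    tm_window: int = 19,
    tm_cutoff: float = 1.6,
) -> ProteinFeatures:
    """Full per-protein feature record used by the pipeline's catalogue."""
    if profile is None:
        profile = default_profile()
    hits = scan_domain(protein, profile)
    return ProteinFeatures(
        id=protein.id,
        length=len(protein.sequence),
        molecular_weight=molecular_weight(protein),
        isoelectric_point=isoelectric_point(protein),
        n_domain_hits=len(hits),
        tm_segments=tuple(find_tm_segments(protein, tm_window, tm_cutoff)),
    )
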
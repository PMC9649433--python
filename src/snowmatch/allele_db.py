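"""Catalogue of per-allele solvent-accessibility profiles.

All alleles of one locus group (HLA Class I here) live on a shared alignment
grid so that positions are comparable across alleles and across loci.  For
alleles without an experimental structure the accessibility profile is
extrapolated by a pluggable sequence-to-surface predictor; the reference
implementation averages the profiles of the k most sequence-similar alleles.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align, SeqIO

GAP = "-"
DEFAULT_SURFACE_THRESHOLD = 0.3717  # reference-panel median RSA
RSA_CLIP = 1.5
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


class AlignmentRejected(ValueError):
    """Query sequence too dissimilar from the grid consensus."""


class GridMismatch(ValueError):
    """Profile or sequence does not live on the expected grid."""


@dataclass(frozen=True)
class AlignmentGrid:
    """Common coordinate system of one locus group."""

    locus_group: str
    consensus: str

    @property
    def n_positions(self) -> int:
        return len(self.consensus)


@dataclass
class AlleleProfile:
    """One allele's aligned sequence and per-position RSA.

    ``rsa`` has grid length; NaN marks positions where the residue is absent
    (gap or unresolved density) — never 0, which means genuinely buried.
    """

    allele: str
    aligned_sequence: str
    rsa: np.ndarray
    provenance: str = "experimental"  # or "predicted"

    def __post_init__(self) -> None:
        self.rsa = np.asarray(self.rsa, dtype=float)
        if len(self.aligned_sequence) != self.rsa.shape[0]:
            raise GridMismatch(
                f"{self.allele}: sequence length {len(self.aligned_sequence)} "
                f"!= rsa length {self.rsa.shape[0]}"
            )
        gaps = np.array([c == GAP for c in self.aligned_sequence])
        if np.any(~np.isnan(self.rsa[gaps])):
            raise ValueError(f"{self.allele}: rsa defined at gap positions")
        with np.errstate(invalid="ignore"):
            if np.any(self.rsa < 0) or np.any(self.rsa > RSA_CLIP):
                raise ValueError(f"{self.allele}: rsa outside [0, {RSA_CLIP}]")

    def residue_at(self, position: int) -> str:
        """1-based mature position -> residue (possibly the gap symbol)."""
        return self.aligned_sequence[position - 1]


def align_to_grid(sequence: str, grid: AlignmentGrid, min_identity: float = 0.70) -> str:
    """Globally align a raw sequence onto the grid; returns a grid-length string.

    Columns of the consensus receive the aligned residue or the gap symbol;
    insertions relative to the consensus are dropped.  Identity to the
    consensus below ``min_identity`` raises :class:`AlignmentRejected` (the
    sequence likely belongs to a different locus group).
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-amino-acid symbols in sequence: {sorted(bad)}")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(grid.consensus, sequence)[0]
    cons_aln, seq_aln = str(aln[0]), str(aln[1])

    out = []
    matches = 0
    for c, s in zip(cons_aln, seq_aln):
        if c == GAP:
            continue  # insertion relative to the grid
        out.append(s if s != GAP else GAP)
        if s == c:
            matches += 1
    identity = matches / grid.n_positions
    if identity < min_identity:
        raise AlignmentRejected(
            f"identity to consensus {identity:.2f} < {min_identity:.2f}"
        )
    return "".join(out)


def sequence_identity(a: str, b: str) -> float:
    """Fraction of equal non-gap columns between two grid-aligned sequences."""
    pairs = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
    if not pairs:
        return 0.0
    return sum(x == y for x, y in pairs) / len(pairs)


class KNearestAccessibilityPredictor:
    """Sequence-to-surface predictor: position-wise mean RSA of the k
    most similar training alleles (global identity on the grid, ties broken
    by allele name).

    Satisfies the accessibility-predictor contract: deterministic after
    fitting, and with k=1 a training sequence is recalled verbatim.  A learned
    model (e.g. a neural network) can be dropped in behind the same
    fit/predict surface.
    """

    def __init__(self, k: int = 3):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k

    def fit(self, training: Sequence[AlleleProfile], grid: AlignmentGrid):
        if not training:
            raise ValueError("training set must be non-empty")
        for p in training:
            if len(p.aligned_sequence) != grid.n_positions:
                raise GridMismatch(f"profile {p.allele} not on grid")
        self.grid_ = grid
        self.training_ = sorted(training, key=lambda p: p.allele)
        return self

    def predict(self, aligned_sequence: str) -> np.ndarray:
        """Per-position RSA for a grid-aligned sequence (NaN at gaps)."""
        if not hasattr(self, "training_"):
            raise RuntimeError("predictor is not fitted")
        if len(aligned_sequence) != self.grid_.n_positions:
            raise GridMismatch("query sequence not on the predictor grid")
        sims = np.array(
            [sequence_identity(aligned_sequence, p.aligned_sequence) for p in self.training_]
        )
        # stable sort on (-similarity, name-order) -> deterministic ties
        order = np.argsort(-sims, kind="stable")
        chosen = [self.training_[i] for i in order[: self.k]]
        stack = np.vstack([p.rsa for p in chosen])
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(stack, axis=0)
        gaps = np.array([c == GAP for c in aligned_sequence])
        mean[gaps] = np.nan
        return np.clip(mean, 0.0, RSA_CLIP)

    def neighbours(self, aligned_sequence: str) -> list[AlleleProfile]:
        sims = np.array(
            [sequence_identity(aligned_sequence, p.aligned_sequence) for p in self.training_]
        )
        order = np.argsort(-sims, kind="stable")
        return [self.training_[i] for i in order[: self.k]]


def fit_predictor(
    training: Sequence[AlleleProfile], grid: AlignmentGrid, k: int = 3
) -> KNearestAccessibilityPredictor:
    return KNearestAccessibilityPredictor(k=k).fit(training, grid)


def predict_profile(
    predictor: KNearestAccessibilityPredictor, allele: str, aligned_sequence: str
) -> AlleleProfile:
    rsa = predictor.predict(aligned_sequence)
    return AlleleProfile(
        allele=allele, aligned_sequence=aligned_sequence, rsa=rsa, provenance="predicted"
    )


def surface_positions(
    profile: AlleleProfile, threshold: float = DEFAULT_SURFACE_THRESHOLD
) -> set[int]:
    """1-based mature positions with RSA >= threshold; gaps never included."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    with np.errstate(invalid="ignore"):
        mask = np.asarray(profile.rsa) >= threshold
    return {int(i) + 1 for i in np.flatnonzero(mask)}


class AlleleDatabase:
    """Allele name -> profile, all on one grid; collisions are errors."""

    def __init__(self, grid: AlignmentGrid, profiles: Iterable[AlleleProfile] = ()):
        self.grid = grid
        self._profiles: dict[str, AlleleProfile] = {}
        for p in profiles:
            self.add(p)

    def add(self, profile: AlleleProfile) -> None:
        if len(profile.aligned_sequence) != self.grid.n_positions:
            raise GridMismatch(f"profile {profile.allele} not on grid")
        if profile.allele in self._profiles:
            raise ValueError(f"duplicate allele profile: {profile.allele}")
        self._profiles[profile.allele] = profile

    def __contains__(self, allele: str) -> bool:
        return allele in self._profiles

    def __len__(self) -> int:
        return len(self._profiles)

    def alleles(self) -> list[str]:
        return sorted(self._profiles)

    def get(self, allele: str) -> AlleleProfile:
        try:
            return self._profiles[allele]
        except KeyError:
            raise KeyError(f"allele {allele!r} not in database") from None

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["allele", "position", "residue", "rsa", "provenance"])
            for name in self.alleles():
                p = self._profiles[name]
                for i, res in enumerate(p.aligned_sequence):
                    rsa = p.rsa[i]
                    w.writerow(
                        [name, i + 1, res, "" if np.isnan(rsa) else f"{rsa:.6f}", p.provenance]
                    )

    @classmethod
    def from_csv(cls, path, locus_group: str = "classI") -> "AlleleDatabase":
        rows: dict[str, list[tuple[int, str, float]]] = {}
        prov: dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                rsa = float(row["rsa"]) if row["rsa"] != "" else np.nan
                rows.setdefault(row["allele"], []).append(
                    (int(row["position"]), row["residue"], rsa)
                )
                prov[row["allele"]] = row["provenance"]
        profiles = []
        n_positions = None
        for allele, entries in rows.items():
            entries.sort()
            seq = "".join(e[1] for e in entries)
            rsa = np.array([e[2] for e in entries])
            if n_positions is None:
                n_positions = len(seq)
            profiles.append(
                AlleleProfile(allele=allele, aligned_sequence=seq, rsa=rsa, provenance=prov[allele])
            )
        # consensus = modal residue per column over the stored alleles
        if not profiles:
            raise ValueError(f"no profiles in {path}")
        cols = np.array([list(p.aligned_sequence) for p in profiles])
        consensus = "".join(
            max(set(col), key=lambda c: (list(col).count(c), c)) for col in cols.T
        )
        grid = AlignmentGrid(locus_group=locus_group, consensus=consensus)
        return cls(grid, profiles)


def build_database(
    sequences: Mapping[str, str],
    grid: AlignmentGrid,
    experimental: Mapping[str, np.ndarray],
    k: int = 3,
) -> AlleleDatabase:
    """Assemble a full-coverage database from sequences plus the subset of
    alleles with measured surfaces; the rest are filled in by the predictor.
    """
    training = []
    for name, rsa in experimental.items():
        training.append(
            AlleleProfile(
                allele=name,
                aligned_sequence=align_to_grid(sequences[name].replace(GAP, ""), grid)
                if GAP in sequences[name] or len(sequences[name]) != grid.n_positions
                else sequences[name],
                rsa=rsa,
            )
        )
    predictor = fit_predictor(training, grid, k=k)
    db = AlleleDatabase(grid)
    for p in training:
        db.add(p)
    for name, seq in sequences.items():
        if name in db:
            continue
        aligned = seq if len(seq) == grid.n_positions else align_to_grid(seq, grid)
        db.add(predict_profile(predictor, name, aligned))
    return db


def read_fasta_sequences(path) -> dict[str, str]:
    """FASTA with the allele name as header."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
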
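"""Epitope mismatch scoring between immunizer and responder HLA genotypes.

Three score families are computed for donor/recipient (or child/mother)
pairs, per Class I locus:

* **Snowflake** — count of (position, residue) pairs on the donor allele's
  *own* solvent-accessible surface whose residue is absent from every allele
  of the recipient's Class I repertoire.  The surface is allele-specific:
  accessible positions come from the donor allele's RSA profile, not from a
  locus-wide map.
* **AllEPS / AbvEPS** — mismatched eplets of a registry (all, respectively
  antibody-verified only): an eplet counts when present on at least one donor
  allele of the locus and on none of the recipient's Class I alleles.
* **PIRCHE surrogate** — donor-peptide presentation counts: core-length
  windows of the donor sequence containing at least one mismatched residue,
  filtered by a pluggable presentation predicate per presenter locus.  The
  default predicate accepts every peptide; real peptide-MHC binding
  prediction plugs in behind the same interface.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import pandas as pd

from .allele_db import GAP, AlleleDatabase, DEFAULT_SURFACE_THRESHOLD, surface_positions

CLASS_I_LOCI = ("A", "B", "C")
DEFAULT_PRESENTER_LOCI = ("DRB1", "DRB345", "DQ", "DP")
DEFAULT_CORE_LENGTH = 9

PresentationPredicate = Callable[[str, str], bool]


def accept_all(peptide: str, presenter: str) -> bool:  # noqa: ARG001
    """Default presentation predicate: every peptide is presented."""
    return True


@dataclass(frozen=True)
class EpletDefinition:
    name: str
    pattern: frozenset[tuple[int, str]]  # (1-based mature position, residue)
    antibody_verified: bool

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"eplet {self.name}: empty pattern")


@dataclass
class LocusScoreSet:
    case_id: str
    locus: str
    snowflake: int
    all_eps: int
    abv_eps: int
    pirche: dict[str, int] = field(default_factory=dict)  # presenter locus -> count
    outcome: bool | None = None

    def __post_init__(self) -> None:
        if self.abv_eps > self.all_eps:
            raise ValueError("abv_eps cannot exceed all_eps")


_TOKEN_RE = re.compile(r"^(\d+)([A-Z])$")


class RegistryError(ValueError):
    pass


def load_eplet_registry(path) -> list[EpletDefinition]:
    """Parse an eplet registry CSV: name, verified flag, pattern tokens.

    Pattern tokens are space-separated position+residue strings ("62G 63E").
    """
    eplets: list[EpletDefinition] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            name = row["name"].strip()
            if name in seen:
                raise RegistryError(f"line {lineno}: duplicate eplet name {name!r}")
            seen.add(name)
            verified = str(row["verified"]).strip().lower() in {"true", "1", "yes"}
            tokens = row["pattern"].split()
            if not tokens:
                raise RegistryError(f"line {lineno}: empty pattern for {name!r}")
            pattern = set()
            for tok in tokens:
                m = _TOKEN_RE.match(tok.strip())
                if not m:
                    raise RegistryError(f"line {lineno}: malformed token {tok!r}")
                pattern.add((int(m.group(1)), m.group(2)))
            eplets.append(
                EpletDefinition(name=name, pattern=frozenset(pattern), antibody_verified=verified)
            )
    return eplets


def write_eplet_registry(path, eplets: Sequence[EpletDefinition]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "verified", "pattern"])
        for e in eplets:
            toks = " ".join(f"{p}{r}" for p, r in sorted(e.pattern))
            w.writerow([e.name, str(e.antibody_verified).lower(), toks])


def _recipient_residues(db: AlleleDatabase, recipient_alleles: Sequence[str]) -> list[set[str]]:
    """Per grid position (0-based), the set of residues the recipient carries."""
    n = db.grid.n_positions
    residues: list[set[str]] = [set() for _ in range(n)]
    for name in recipient_alleles:
        seq = db.get(name).aligned_sequence
        for i, res in enumerate(seq):
            if res != GAP:
                residues[i].add(res)
    return residues


def mismatched_surface_pairs(
    donor_allele: str,
    recipient_alleles: Sequence[str],
    db: AlleleDatabase,
    threshold: float = DEFAULT_SURFACE_THRESHOLD,
) -> set[tuple[int, str]]:
    """(position, residue) pairs on the donor allele's accessible surface
    absent from every recipient allele at that position.

    A donor allele that also appears in the recipient repertoire contributes
    nothing (allele-matched pairs score zero by design).
    """
    if donor_allele in set(recipient_alleles):
        return set()
    profile = db.get(donor_allele)
    recipient = _recipient_residues(db, recipient_alleles)
    pairs: set[tuple[int, str]] = set()
    for pos in surface_positions(profile, threshold):
        res = profile.residue_at(pos)
        if res == GAP:
            continue
        if res not in recipient[pos - 1]:
            pairs.add((pos, res))
    return pairs


def snowflake_score(
    donor_alleles: Sequence[str],
    recipient_alleles: Sequence[str],
    db: AlleleDatabase,
    threshold: float = DEFAULT_SURFACE_THRESHOLD,
) -> int:
    """Locus-level Snowflake score: size of the union of mismatched
    (position, residue) pairs over the locus's donor alleles.

    ``recipient_alleles`` is the comparison repertoire: the recipient's full
    Class I set for interlocus scoring, or the same-locus pair for
    intralocus scoring.  Union (not sum) avoids double-counting a mismatch
    shared by both donor alleles — scores are locus-specific, not
    mismatch-specific.
    """
    pairs: set[tuple[int, str]] = set()
    for donor in set(donor_alleles):
        pairs |= mismatched_surface_pairs(donor, recipient_alleles, db, threshold)
    return len(pairs)


def eplet_present(eplet: EpletDefinition, aligned_sequence: str) -> bool:
    """True iff every (position, residue) of the pattern matches the sequence."""
    n = len(aligned_sequence)
    for pos, res in eplet.pattern:
        if not 1 <= pos <= n:
            raise RegistryError(f"eplet {eplet.name}: position {pos} off-grid (1..{n})")
        if aligned_sequence[pos - 1] != res:
            return False
    return True


def eplet_mismatch_count(
    donor_alleles: Sequence[str],
    recipient_alleles: Sequence[str],
    db: AlleleDatabase,
    registry: Sequence[EpletDefinition],
    verified_only: bool = False,
) -> int:
    """Number of distinct eplets present on >=1 donor allele of the locus and
    absent from every recipient allele (the recipient's six Class I alleles
    for interlocus counting)."""
    donor_seqs = [db.get(a).aligned_sequence for a in set(donor_alleles)]
    recip_seqs = [db.get(a).aligned_sequence for a in set(recipient_alleles)]
    count = 0
    for eplet in registry:
        if verified_only and not eplet.antibody_verified:
            continue
        if not any(eplet_present(eplet, s) for s in donor_seqs):
            continue
        if any(eplet_present(eplet, s) for s in recip_seqs):
            continue
        count += 1
    return count


def pirche_like_count(
    donor_allele: str,
    recipient_class_I: Sequence[str],
    presenter_alleles: Mapping[str, Sequence[str]],
    db: AlleleDatabase,
    presentation_predicate: PresentationPredicate = accept_all,
    core_length: int = DEFAULT_CORE_LENGTH,
) -> dict[str, int]:
    """Donor-derived mismatched-peptide counts per presenter locus.

    Every ``core_length``-mer of the donor's ungapped sequence containing at
    least one residue absent at that grid position from every recipient
    Class I allele is a candidate; candidates accepted by the presentation
    predicate are counted for each presenter locus.  This is a surrogate for
    indirect T-cell epitope prediction — the predicate is where a real
    peptide-MHC binding model plugs in.
    """
    profile = db.get(donor_allele)
    if donor_allele in set(recipient_class_I):
        return {locus: 0 for locus in presenter_alleles}
    recipient = _recipient_residues(db, recipient_class_I)

    # ungapped donor sequence with its grid positions
    residues: list[tuple[int, str]] = [
        (i, r) for i, r in enumerate(profile.aligned_sequence) if r != GAP
    ]
    seq = "".join(r for _, r in residues)
    if core_length > len(seq):
        warnings.warn(
            f"core_length {core_length} exceeds sequence length {len(seq)}", stacklevel=2
        )
        return {locus: 0 for locus in presenter_alleles}

    mismatched = [r not in recipient[i] for i, r in residues]
    counts: dict[str, int] = {}
    for locus, presenters in presenter_alleles.items():
        # an unspecified presenter genotype still exercises the predicate once
        plist = tuple(presenters) or ("",)
        n = 0
        for start in range(len(seq) - core_length + 1):
            if not any(mismatched[start : start + core_length]):
                continue
            peptide = seq[start : start + core_length]
            if any(presentation_predicate(peptide, p) for p in plist):
                n += 1
        counts[locus] = n
    return counts


Genotype = Mapping[str, tuple[str, str]]  # locus -> allele pair


def locus_scores(
    case_id: str,
    donor: Genotype,
    recipient: Genotype,
    db: AlleleDatabase,
    registry: Sequence[EpletDefinition],
    presenter_alleles: Mapping[str, Sequence[str]] | None = None,
    threshold: float = DEFAULT_SURFACE_THRESHOLD,
    mode: str = "interlocus",
    presentation_predicate: PresentationPredicate = accept_all,
    core_length: int = DEFAULT_CORE_LENGTH,
) -> list[LocusScoreSet]:
    """All four score families for each Class I locus of one pair.

    ``mode='interlocus'`` compares each donor allele against the recipient's
    full A/B/C repertoire; ``'intralocus'`` restricts the comparison to the
    recipient's same-locus pair.  Eplet counts are always interlocus.
    """
    if mode not in ("interlocus", "intralocus"):
        raise ValueError(f"unknown mode {mode!r}")
    recipient_all = [a for locus in CLASS_I_LOCI for a in recipient[locus]]
    if presenter_alleles is None:
        presenter_alleles = {locus: () for locus in DEFAULT_PRESENTER_LOCI}

    out: list[LocusScoreSet] = []
    for locus in CLASS_I_LOCI:
        donor_pair = list(donor[locus])
        comparison = list(recipient[locus]) if mode == "intralocus" else recipient_all
        snow = snowflake_score(donor_pair, comparison, db, threshold)
        all_eps = eplet_mismatch_count(donor_pair, recipient_all, db, registry)
        abv_eps = eplet_mismatch_count(
            donor_pair, recipient_all, db, registry, verified_only=True
        )
        pirche: dict[str, int] = {k: 0 for k in presenter_alleles}
        for allele in set(donor_pair):
            c = pirche_like_count(
                allele, recipient_all, presenter_alleles, db,
                presentation_predicate, core_length,
            )
            for k, v in c.items():
                pirche[k] += v
        out.append(
            LocusScoreSet(
                case_id=case_id, locus=locus, snowflake=snow,
                all_eps=all_eps, abv_eps=abv_eps, pirche=pirche,
            )
        )
    return out


def score_pairs_table(
    pairs: pd.DataFrame,
    db: AlleleDatabase,
    registry: Sequence[EpletDefinition],
    threshold: float = DEFAULT_SURFACE_THRESHOLD,
    mode: str = "interlocus",
    presenter_loci: Sequence[str] = DEFAULT_PRESENTER_LOCI,
) -> pd.DataFrame:
    """Batch scoring of a pairs table (CSV-friendly; mirrors the web-service
    batch format).

    Input columns: ``case_id`` plus ``donor_<L>_1/2`` and ``recipient_<L>_1/2``
    for each Class I locus L.  Output: one row per case and locus with the
    four score families.
    """
    rows = []
    presenters = {k: () for k in presenter_loci}
    for _, row in pairs.iterrows():
        donor = {L: (row[f"donor_{L}_1"], row[f"donor_{L}_2"]) for L in CLASS_I_LOCI}
        recip = {L: (row[f"recipient_{L}_1"], row[f"recipient_{L}_2"]) for L in CLASS_I_LOCI}
        for s in locus_scores(
            str(row["case_id"]), donor, recip, db, registry,
            presenter_alleles=presenters, threshold=threshold, mode=mode,
        ):
            rec = {
                "case_id": s.case_id, "locus": s.locus, "snowflake": s.snowflake,
                "all_eps": s.all_eps, "abv_eps": s.abv_eps,
            }
            for k, v in s.pirche.items():
                rec[f"pirche_{k}"] = v
            rows.append(rec)
    return pd.DataFrame(rows)
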
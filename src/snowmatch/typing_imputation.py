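"""Haplotype-frequency imputation of ambiguous HLA typings.

Intermediate-resolution typings (serologic antigens, multiple-allele codes)
are resolved to weighted high-resolution genotypes: candidate haplotype pairs
consistent with the observed typing are enumerated from a population
haplotype-frequency table, weighted by Hardy-Weinberg pair probability,
filtered at a normalized-frequency floor, and renormalized.  Epitope scores
are then frequency-weighted expectations over the retained candidates.
"""

from __future__ import annotations

import csv
import itertools
import re
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_MIN_NORM_FREQ = 0.01  # candidates kept only if weight strictly exceeds this


class UnresolvedTyping(ValueError):
    pass


class ImputationFailure(ValueError):
    pass


@dataclass(frozen=True)
class Haplotype:
    alleles: tuple[str, ...]  # one allele per locus, fixed locus order
    frequency: float

    def __post_init__(self) -> None:
        if not 0 < self.frequency <= 1:
            raise ValueError(f"haplotype frequency must be in (0, 1], got {self.frequency}")


@dataclass(frozen=True)
class WeightedGenotype:
    """A candidate pair of haplotypes with its normalized weight."""

    haplotypes: tuple[Haplotype, Haplotype]
    weight: float

    def genotype(self, loci: Sequence[str]) -> dict[str, tuple[str, str]]:
        h1, h2 = self.haplotypes
        return {
            locus: tuple(sorted((h1.alleles[i], h2.alleles[i])))
            for i, locus in enumerate(loci)
        }


def load_mac_table(path) -> dict[str, list[str]]:
    """CSV ``code,alleles`` with pipe-separated allele lists."""
    table: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            alleles = [a.strip() for a in row["alleles"].split("|") if a.strip()]
            if not alleles:
                raise ValueError(f"MAC code {row['code']!r} has an empty expansion")
            table[row["code"].strip().upper()] = alleles
    return table


def load_serology_map(path) -> dict[str, str]:
    """CSV ``allele,antigen``: allele -> serologic (split) equivalent."""
    with open(path, newline="") as fh:
        return {row["allele"].strip(): row["antigen"].strip() for row in csv.DictReader(fh)}


def load_haplotype_table(path, loci: Sequence[str]) -> list[Haplotype]:
    """CSV with one column per locus plus ``frequency``."""
    haps = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            haps.append(
                Haplotype(
                    alleles=tuple(row[locus].strip() for locus in loci),
                    frequency=float(row["frequency"]),
                )
            )
    total = sum(h.frequency for h in haps)
    if total > 1 + 1e-6:
        raise ValueError(f"haplotype frequencies sum to {total:.4f} > 1")
    return haps


_EXPLICIT_RE = re.compile(r"^[A-Z0-9]+\*\d+:\d+[A-Z]?$")


def expand_mac(
    typing_token: str,
    mac: Mapping[str, Sequence[str]],
    serology_map: Mapping[str, str] | None = None,
) -> list[str]:
    """Expand one typing token into its candidate allele list.

    Explicit two-field alleles pass through as singletons; MAC codes expand
    via the code table; serologic antigens expand to every allele mapping to
    that antigen.  Unknown tokens raise :class:`UnresolvedTyping`.
    """
    token = typing_token.strip()
    code = token.upper()
    if code in mac:
        return list(mac[code])
    if _EXPLICIT_RE.match(token):
        return [token]
    if serology_map:
        alleles = sorted(a for a, ag in serology_map.items() if ag == token)
        if alleles:
            return alleles
    raise UnresolvedTyping(f"cannot resolve typing token {token!r}")


def _pair_matches_typing(
    pair_alleles: tuple[str, str], expansions: tuple[set[str], set[str]]
) -> bool:
    a1, a2 = pair_alleles
    e1, e2 = expansions
    return (a1 in e1 and a2 in e2) or (a1 in e2 and a2 in e1)


def genotype_candidates(
    typing: Mapping[str, tuple[str, str]],
    haplotypes: Sequence[Haplotype],
    loci: Sequence[str],
    mac: Mapping[str, Sequence[str]],
    serology_map: Mapping[str, str],
    min_norm_freq: float = DEFAULT_MIN_NORM_FREQ,
) -> list[WeightedGenotype]:
    """Weighted high-resolution genotype candidates for one ambiguous typing.

    Haplotype pairs are weighted f(h1)*f(h2), doubled for heterozygous pairs
    (Hardy-Weinberg), normalized over all typing-consistent pairs, filtered
    at strictly greater than ``min_norm_freq``, and renormalized to sum 1.
    """
    expansions = {
        locus: tuple(
            set(expand_mac(tok, mac, serology_map)) for tok in typing[locus]
        )
        for locus in loci
    }
    candidates: list[tuple[tuple[Haplotype, Haplotype], float]] = []
    for i, j in itertools.combinations_with_replacement(range(len(haplotypes)), 2):
        h1, h2 = haplotypes[i], haplotypes[j]
        ok = all(
            _pair_matches_typing(
                (h1.alleles[k], h2.alleles[k]), expansions[locus]
            )
            for k, locus in enumerate(loci)
        )
        if not ok:
            continue
        w = h1.frequency * h2.frequency * (2.0 if i != j else 1.0)
        candidates.append(((h1, h2), w))

    if not candidates:
        raise ImputationFailure("no haplotype pair is consistent with the typing")

    total = sum(w for _, w in candidates)
    normalized = [(pair, w / total) for pair, w in candidates]
    retained = [(pair, w) for pair, w in normalized if w > min_norm_freq]
    if not retained:
        raise ImputationFailure(
            f"all candidate pairs fall at or below the {min_norm_freq:.2%} floor"
        )
    kept_total = sum(w for _, w in retained)
    return [
        WeightedGenotype(haplotypes=pair, weight=w / kept_total) for pair, w in retained
    ]


def imputed_score(
    donor_candidates: Sequence[WeightedGenotype],
    recipient_candidates: Sequence[WeightedGenotype],
    scorer: Callable[[WeightedGenotype, WeightedGenotype], np.ndarray],
) -> np.ndarray:
    """Frequency-weighted expected score over donor x recipient candidates.

    Donor and recipient imputations are treated as independent, so the
    combination weight is the product of the candidate weights.  Applies to
    every score family identically (``scorer`` may return a vector).
    """
    for cands, side in ((donor_candidates, "donor"), (recipient_candidates, "recipient")):
        s = sum(c.weight for c in cands)
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"{side} candidate weights sum to {s}, expected 1")
    result = None
    for d in donor_candidates:
        for r in recipient_candidates:
            contrib = d.weight * r.weight * np.asarray(scorer(d, r), dtype=float)
            result = contrib if result is None else result + contrib
    return result


def serologic_view(
    genotype: Mapping[str, tuple[str, str]], serology_map: Mapping[str, str]
) -> dict[str, tuple[str, str]]:
    """Degrade a high-resolution genotype to serologic antigens; unmapped
    alleles fail loudly."""
    out = {}
    for locus, pair in genotype.items():
        try:
            out[locus] = tuple(serology_map[a] for a in pair)
        except KeyError as exc:
            raise UnresolvedTyping(f"allele {exc.args[0]!r} has no serologic mapping") from None
    return out
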
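"""Synthetic fixtures: allele pools, toy structures, registries and cohorts.

Everything the pipeline consumes can be generated here, seeded and
deterministic: a panel of toy Class I alleles on a shared grid with known
("true") accessibility profiles, idealized helical structures for a subset of
alleles, an eplet registry derived from the panel's surface polymorphisms,
haplotype-frequency / multi-allele-code / serology tables, and two cohort
designs — mother/child pregnancies with logistic antibody outcomes and
donor/recipient transplants with exponential time-to-antibody outcomes, both
driven by the standardized true Snowflake score.

The generators emulate the *designs* of the clinical cohorts (haplotype
transmission, ambiguous typing, locus-level antibody calls), not real HLA
sequences, frequencies or registry content.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder
from Bio.Data.IUPACData import protein_letters_1to3
from scipy.special import expit

from .allele_db import (
    GAP,
    AlignmentGrid,
    AlleleDatabase,
    AlleleProfile,
    DEFAULT_SURFACE_THRESHOLD,
)
from .epitope_matching import (
    CLASS_I_LOCI,
    EpletDefinition,
    locus_scores,
    write_eplet_registry,
)
from .structure_surface import (
    AtomRecord,
    compute_sasa,
    load_max_asa,
    load_vdw_radii,
    residue_surfaces,
)
from .typing_imputation import Haplotype

AA = "ACDEFGHIKLMNPQRSTVWY"
PRESENTER_LOCI = ("DRB1", "DRB345", "DQ", "DP")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    Effect sizes are on the logit / log-hazard scale per 1 SD of the true
    Snowflake score; the defaults emulate an antibody incidence around 20%
    of informative mismatches with an odds ratio of 1.63 per SD, and a
    transplant cohort with a low yearly antibody hazard followed for up to
    15 years.
    """

    seed: int = 0
    n_alleles_per_locus: int = 6
    n_allele_groups: int = 3  # first-field groups per locus (serologic antigens)
    grid_length: int = 50
    surface_fraction: float = 0.4
    polymorphic_fraction: float = 0.6
    n_haplotypes: int = 12
    n_eplets: int | None = None  # None = every surface polymorphism of the panel
    n_structures: int = 3
    n_cases: int = 300
    beta0: float = -1.3  # logit intercept, ~21% baseline antibody rate
    beta_snowflake: float = float(np.log(1.63))
    cross_locus_coupling: float = 0.0  # logit weight of the other loci's mean z-score
    baseline_hazard: float = 0.016  # per year
    beta_hazard: float = float(np.log(1.32))
    censoring_rate: float = 0.3
    max_follow_up: float = 15.0  # years
    mfi_baseline: float = 30.0
    mfi_noise_sd: float = 0.4  # lognormal sigma
    mfi_target_factor: float = 100.0
    surface_threshold: float = DEFAULT_SURFACE_THRESHOLD

    def __post_init__(self) -> None:
        if min(self.n_alleles_per_locus, self.grid_length, self.n_cases,
               self.n_haplotypes) < 1:
            raise ValueError("counts must be positive")
        if self.n_eplets is not None and self.n_eplets < 1:
            raise ValueError("n_eplets must be positive or None")
        for name in ("surface_fraction", "polymorphic_fraction", "censoring_rate"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.mfi_noise_sd <= 0:
            raise ValueError("mfi_noise_sd must be positive")


@dataclass
class AllelePool:
    config: SimulationConfig
    grid: AlignmentGrid
    sequences: dict[str, str]
    true_rsa: dict[str, np.ndarray]
    db: AlleleDatabase
    registry: list[EpletDefinition]
    haplotypes: list[Haplotype]
    loci: tuple[str, ...] = CLASS_I_LOCI
    mac: dict[str, list[str]] = field(default_factory=dict)
    serology: dict[str, str] = field(default_factory=dict)
    structure_alleles: list[str] = field(default_factory=list)
    structure_truth: dict[str, dict[int, float]] = field(default_factory=dict)

    def group_of(self, allele: str) -> str:
        return allele.split(":")[0]


# ---------------------------------------------------------------------------
# toy structures


def toy_structure_atoms(sequence: str, chain_id: str = "A") -> list[AtomRecord]:
    """Idealized alpha-helical backbone with outward side-chain dummy spheres.

    100 degrees of turn and 1.5 A rise per residue on a 2.3 A radius; N, C
    and O sit near the helix axis, CB (plus CG for bulky residues) points
    outward, so side chains are more exposed than the backbone.
    """
    vdw = load_vdw_radii()
    maxasa = load_max_asa()
    one_to_three = {k.upper(): v.upper() for k, v in protein_letters_1to3.items()}
    atoms: list[AtomRecord] = []
    for i, aa in enumerate(sequence):
        theta = np.deg2rad(100.0 * i)
        e = np.array([np.cos(theta), np.sin(theta), 0.0])
        ca = 2.3 * e + np.array([0.0, 0.0, 1.5 * i])
        res3 = one_to_three[aa]
        placements = [
            ("N", "N", ca - 0.8 * e + np.array([0.0, 0.0, -1.2])),
            ("CA", "C", ca),
            ("C", "C", ca - 0.8 * e + np.array([0.0, 0.0, 1.2])),
            ("O", "O", ca - 1.6 * e + np.array([0.0, 0.0, 1.6])),
        ]
        if aa != "G":
            placements.append(("CB", "C", ca + 1.4 * e + np.array([0.0, 0.0, 0.3])))
        if maxasa[aa] > 200.0:  # bulky side chain: one more outward sphere
            placements.append(("CG", "C", ca + 2.8 * e + np.array([0.0, 0.0, 0.5])))
        for name, element, pos in placements:
            atoms.append(
                AtomRecord(
                    chain_id=chain_id,
                    residue_index=i + 1,
                    residue_name=res3,
                    atom_name=name,
                    position=tuple(pos),
                    vdw_radius=vdw[element],
                )
            )
    return atoms


def write_toy_structure(sequence: str, path, chain_id: str = "A") -> None:
    """Write the toy helix as a PDB file (via Biopython's writer)."""
    one_to_three = {k.upper(): v.upper() for k, v in protein_letters_1to3.items()}
    atoms = toy_structure_atoms(sequence, chain_id)
    sb = StructureBuilder()
    sb.init_structure("toy")
    sb.init_model(0)
    sb.init_chain(chain_id)
    sb.init_seg("    ")
    current = None
    for a in atoms:
        if a.residue_index != current:
            sb.init_residue(one_to_three[sequence[a.residue_index - 1]], " ",
                            a.residue_index, " ")
            current = a.residue_index
        element = "O" if a.atom_name.startswith("O") else a.atom_name[0]
        sb.init_atom(
            a.atom_name,
            np.array(a.position, dtype="f"),
            0.0,
            1.0,
            " ",
            f"{a.atom_name:^4s}"[:4],
            element=element,
        )
    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(path))


def structure_rsa_profile(sequence: str) -> dict[int, float]:
    """Computed per-position RSA of the toy structure of ``sequence``."""
    atoms = toy_structure_atoms(sequence)
    sasa = compute_sasa(atoms)
    return {s.mature_position: s.rsa for s in residue_surfaces(atoms, sasa)}


# ---------------------------------------------------------------------------
# allele pool


def _allele_name(locus: str, group: int, sub: int) -> str:
    return f"{locus}*{group:02d}:{sub:02d}"


def make_allele_pool(config: SimulationConfig) -> AllelePool:
    """Generate the complete fixture universe from one seeded config.

    Alleles of all Class I loci share one grid; each allele has exactly
    ``round(surface_fraction * grid_length)`` surface positions (true RSA
    drawn above the threshold there, below it elsewhere), so surface counts
    are exact by construction.  The eplet registry is derived from surface
    polymorphisms, tying eplet and Snowflake scores together by design.
    """
    rng = np.random.default_rng(config.seed)
    L = config.grid_length
    consensus = "".join(rng.choice(list(AA), size=L))
    n_poly = int(round(config.polymorphic_fraction * L))
    poly_positions = np.sort(rng.choice(L, size=n_poly, replace=False))
    # two alternative residues per polymorphic column, shared across alleles
    alternatives = {
        int(p): [aa for aa in rng.permutation(list(AA)) if aa != consensus[p]][:2]
        for p in poly_positions
    }

    n_surface = int(round(config.surface_fraction * L))
    base_priority = rng.permutation(L).astype(float)

    sequences: dict[str, str] = {}
    true_rsa: dict[str, np.ndarray] = {}
    groups = np.arange(config.n_allele_groups) + 1
    for locus in CLASS_I_LOCI:
        for idx in range(config.n_alleles_per_locus):
            group = int(groups[idx % config.n_allele_groups])
            sub = idx // config.n_allele_groups + 1
            name = _allele_name(locus, group, sub)
            seq = list(consensus)
            for p in poly_positions:
                if rng.random() < 0.5:
                    seq[p] = rng.choice(alternatives[int(p)])
            sequences[name] = "".join(seq)
            # allele-specific surface: jitter the shared priority ranking
            priority = base_priority + rng.normal(0.0, 3.0, size=L)
            surf = np.argsort(priority)[:n_surface]
            rsa = rng.uniform(0.0, 0.30, size=L)
            rsa[surf] = rng.uniform(0.45, 1.0, size=n_surface)
            true_rsa[name] = rsa

    grid = AlignmentGrid(locus_group="classI", consensus=consensus)
    db = AlleleDatabase(grid)
    for name in sorted(sequences):
        db.add(AlleleProfile(allele=name, aligned_sequence=sequences[name],
                             rsa=true_rsa[name], provenance="experimental"))

    # eplet registry derived from the panel's surface polymorphisms: one
    # single-residue eplet per (position, residue) configuration observed at a
    # polymorphic position on an allele whose own surface exposes it.  A
    # configuration exposed on *every* carrier allele is antibody-verified
    # (robustly accessible); one exposed only on some carriers stays
    # unverified.  This ties eplet counts — the verified subset most tightly —
    # to solvent-accessible mismatches by construction.
    names = sorted(sequences)
    threshold = config.surface_threshold
    exposed_on: dict[tuple[int, str], int] = {}
    carriers: dict[tuple[int, str], int] = {}
    for allele in names:
        seq, rsa = sequences[allele], true_rsa[allele]
        for p in poly_positions:
            key = (int(p) + 1, seq[p])
            carriers[key] = carriers.get(key, 0) + 1
            if rsa[p] >= threshold:
                exposed_on[key] = exposed_on.get(key, 0) + 1
    ordered = sorted(k for k in exposed_on)
    if config.n_eplets is not None:
        if len(ordered) < config.n_eplets:
            raise ValueError(
                f"grid yields only {len(ordered)} surface polymorphisms, "
                f"fewer than the requested {config.n_eplets} eplets"
            )
        idx = rng.choice(len(ordered), size=config.n_eplets, replace=False)
        ordered = [ordered[i] for i in sorted(idx)]
    registry = [
        EpletDefinition(
            name=f"E{pos}{res}",
            pattern=frozenset({(pos, res)}),
            antibody_verified=exposed_on[(pos, res)] == carriers[(pos, res)],
        )
        for pos, res in ordered
    ]

    # haplotypes: random allele combinations with Dirichlet frequencies
    locus_alleles = {
        locus: sorted(a for a in names if a.startswith(locus + "*"))
        for locus in CLASS_I_LOCI
    }
    combos: set[tuple[str, ...]] = set()
    while len(combos) < config.n_haplotypes:
        combos.add(tuple(
            locus_alleles[locus][int(rng.integers(len(locus_alleles[locus])))]
            for locus in CLASS_I_LOCI
        ))
    freqs = rng.dirichlet(np.ones(config.n_haplotypes) * 2.0)
    haplotypes = [
        Haplotype(alleles=alleles, frequency=float(f))
        for alleles, f in zip(sorted(combos), freqs)
    ]

    # serology: antigen = locus + first field group; MAC: group candidate list
    serology = {a: f"{a.split('*')[0]}{int(a.split('*')[1].split(':')[0])}" for a in names}
    mac: dict[str, list[str]] = {}
    for locus in CLASS_I_LOCI:
        for g in groups:
            members = [a for a in locus_alleles[locus] if a.startswith(f"{locus}*{g:02d}:")]
            if members:
                mac[f"{locus}*{g:02d}:MM".upper()] = members

    structure_alleles = locus_alleles["A"][: config.n_structures]
    structure_truth = {
        a: structure_rsa_profile(sequences[a][:20]) for a in structure_alleles
    }

    return AllelePool(
        config=config, grid=grid, sequences=sequences, true_rsa=true_rsa, db=db,
        registry=registry, haplotypes=haplotypes, mac=mac, serology=serology,
        structure_alleles=structure_alleles, structure_truth=structure_truth,
    )


def write_pool(pool: AllelePool, out_dir) -> None:
    """Emit every table in the formats the other modules read."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "alleles.fasta", "w") as fh:
        for name in sorted(pool.sequences):
            fh.write(f">{name}\n{pool.sequences[name]}\n")
    pool.db.to_csv(out / "profiles.csv")
    write_eplet_registry(out / "eplets.csv", pool.registry)
    pd.DataFrame(
        [
            {**{locus: h.alleles[i] for i, locus in enumerate(pool.loci)},
             "frequency": h.frequency}
            for h in pool.haplotypes
        ]
    ).to_csv(out / "haplotypes.csv", index=False)
    pd.DataFrame(
        [{"code": c, "alleles": "|".join(v)} for c, v in sorted(pool.mac.items())]
    ).to_csv(out / "mac.csv", index=False)
    pd.DataFrame(
        [{"allele": a, "antigen": g} for a, g in sorted(pool.serology.items())]
    ).to_csv(out / "serology.csv", index=False)
    for allele in pool.structure_alleles:
        fname = allele.replace("*", "_").replace(":", "-") + ".pdb"
        write_toy_structure(pool.sequences[allele][:20], out / fname)


# ---------------------------------------------------------------------------
# cohort simulation


def _draw_haplotype(pool: AllelePool, rng: np.random.Generator) -> Haplotype:
    freqs = np.array([h.frequency for h in pool.haplotypes])
    idx = rng.choice(len(pool.haplotypes), p=freqs / freqs.sum())
    return pool.haplotypes[idx]


def _genotype(h1: Haplotype, h2: Haplotype, loci) -> dict[str, tuple[str, str]]:
    return {
        locus: tuple(sorted((h1.alleles[i], h2.alleles[i])))
        for i, locus in enumerate(loci)
    }


def _score_pair(pool: AllelePool, case_id: str, immunizer, responder) -> dict[str, dict]:
    presenters = {k: () for k in PRESENTER_LOCI}
    out = {}
    for s in locus_scores(case_id, immunizer, responder, pool.db, pool.registry,
                          presenter_alleles=presenters,
                          threshold=pool.config.surface_threshold):
        rec = {"snowflake": s.snowflake, "all_eps": s.all_eps, "abv_eps": s.abv_eps}
        for k, v in s.pirche.items():
            rec[f"pirche_{k}"] = v
        out[s.locus] = rec
    return out


def _informative(immunizer: tuple[str, str], responder: tuple[str, str]) -> bool:
    """Mismatched and not homozygous-for-a-shared-allele."""
    if set(immunizer) <= set(responder):
        return False
    if immunizer[0] == immunizer[1] and immunizer[0] in responder:
        return False
    return True


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    if sd == 0:
        return np.zeros_like(values, dtype=float)
    return (values - values.mean()) / sd


def simulate_pregnancy(pool: AllelePool, config: SimulationConfig | None = None,
                       seed: int | None = None) -> list[dict]:
    """Mother/child cases with logistic per-locus antibody outcomes.

    The mother carries two haplotypes drawn from the frequency table; the
    child inherits one of them plus an independently drawn (paternal)
    haplotype.  For every informative locus (mismatched, non-homozygous) a
    child-specific antibody is drawn Bernoulli with
    logit p = beta0 + beta_snowflake * z(true Snowflake), the z-score taken
    over the cohort's informative records of that locus.  Matched or
    homozygous loci never develop a CSA.
    """
    config = config or pool.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    cases = []
    for i in range(config.n_cases):
        m1, m2 = _draw_haplotype(pool, rng), _draw_haplotype(pool, rng)
        transmitted = m1 if rng.random() < 0.5 else m2
        paternal = _draw_haplotype(pool, rng)
        mother = _genotype(m1, m2, pool.loci)
        child = _genotype(transmitted, paternal, pool.loci)
        case_id = f"PC{i:04d}"
        cases.append({
            "case_id": case_id,
            "mother": mother,
            "child": child,
            "scores": _score_pair(pool, case_id, child, mother),
            "csa": {locus: False for locus in pool.loci},
        })

    # per-case standardized true score by locus (NaN where uninformative)
    z_by_locus: dict[str, np.ndarray] = {}
    for locus in pool.loci:
        informative = np.array([
            _informative(c["child"][locus], c["mother"][locus]) for c in cases
        ])
        z = np.full(len(cases), np.nan)
        if informative.sum() > 1:
            snow = np.array([
                c["scores"][locus]["snowflake"] for c in cases
            ], dtype=float)
            z[informative] = _standardize(snow[informative])
        z_by_locus[locus] = z

    for locus in pool.loci:
        z = z_by_locus[locus]
        informative = np.flatnonzero(~np.isnan(z))
        logit = config.beta0 + config.beta_snowflake * z[informative]
        if config.cross_locus_coupling != 0.0:
            others = np.vstack([z_by_locus[L] for L in pool.loci if L != locus])
            valid = ~np.isnan(others)
            other_mean = np.where(valid, others, 0.0).sum(axis=0) / np.maximum(
                valid.sum(axis=0), 1
            )
            other_mean = other_mean[informative]
            logit = logit + config.cross_locus_coupling * other_mean
        draws = rng.random(informative.size) < expit(logit)
        for j, hit in zip(informative, draws):
            cases[j]["csa"][locus] = bool(hit)
    return cases


def simulate_ktc(pool: AllelePool, config: SimulationConfig | None = None,
                 seed: int | None = None) -> list[dict]:
    """Donor/recipient cases with exponential time-to-DSA outcomes and a
    degraded (ambiguous) typing view.

    Event times per informative locus follow an exponential hazard
    baseline_hazard * exp(beta_hazard * z(true Snowflake)); independent
    exponential censoring is tuned to the configured censoring fraction and
    capped at ``max_follow_up``.  The degraded typing replaces alleles by
    serologic antigens or multi-allele codes so the imputation module can be
    exercised against known truth.
    """
    config = config or pool.config
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    cases = []
    for i in range(config.n_cases):
        d1, d2 = _draw_haplotype(pool, rng), _draw_haplotype(pool, rng)
        r1, r2 = _draw_haplotype(pool, rng), _draw_haplotype(pool, rng)
        donor = _genotype(d1, d2, pool.loci)
        recipient = _genotype(r1, r2, pool.loci)
        case_id = f"KTC{i:04d}"

        def degrade(genotype):
            out = {}
            for locus, pair in genotype.items():
                tokens = []
                for a in pair:
                    u = rng.random()
                    if u < 0.4:
                        tokens.append(pool.serology[a])
                    elif u < 0.8:
                        tokens.append(f"{pool.group_of(a)}:MM")
                    else:
                        tokens.append(a)
                out[locus] = tuple(tokens)
            return out

        cases.append({
            "case_id": case_id,
            "donor": donor,
            "recipient": recipient,
            "donor_typing": degrade(donor),
            "recipient_typing": degrade(recipient),
            "scores": _score_pair(pool, case_id, donor, recipient),
            "dsa": {locus: False for locus in pool.loci},
            "follow_up": {locus: 0.0 for locus in pool.loci},
        })

    c = config.censoring_rate
    censor_rate = config.baseline_hazard * c / (1.0 - c)
    for locus in pool.loci:
        snow = np.array([c_["scores"][locus]["snowflake"] for c_ in cases], dtype=float)
        retained = np.array([
            any(v > 0 for v in c_["scores"][locus].values()) for c_ in cases
        ])
        z = np.zeros(len(cases))
        if retained.sum() > 1:
            z[retained] = _standardize(snow[retained])
        hazard = config.baseline_hazard * np.exp(config.beta_hazard * z)
        t_event = rng.exponential(1.0 / hazard)
        t_censor = np.minimum(
            rng.exponential(1.0 / censor_rate, size=len(cases))
            if censor_rate > 0 else np.full(len(cases), np.inf),
            config.max_follow_up,
        )
        for j, case in enumerate(cases):
            observed = min(t_event[j], t_censor[j])
            case["follow_up"][locus] = float(max(observed, 1e-6))
            case["dsa"][locus] = bool(t_event[j] <= t_censor[j])
    return cases


# ---------------------------------------------------------------------------
# single-antigen-bead simulation


def simulate_sab(
    bead_alleles: list[str],
    self_alleles: set[str],
    true_targets: set[str],
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Simulate an MFI panel and call antibodies with the sample-specific
    biological cutoff: MFI above 100 *and* exceeding mean(self beads) + 3 SD.

    Self beads and non-target beads fluoresce at a log-normal baseline;
    true-target beads are elevated by ``mfi_target_factor``.  Returns the
    bead table and the called allele list; an independent re-evaluation of
    the cutoff on the emitted table must reproduce the calls exactly.
    """
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    n_self = sum(1 for a in bead_alleles if a in self_alleles)
    if n_self < 2:
        raise ValueError("cutoff undefined: fewer than 2 self beads on the panel")
    rows = []
    for allele in bead_alleles:
        mu = config.mfi_baseline
        if allele in true_targets and allele not in self_alleles:
            mu *= config.mfi_target_factor
        mfi = float(np.exp(np.log(mu) + rng.normal(0.0, config.mfi_noise_sd)))
        rows.append({"allele": allele, "mfi": mfi, "is_self": allele in self_alleles})
    panel = pd.DataFrame(rows)
    called = call_antibodies(panel)
    return panel, called


def call_antibodies(panel: pd.DataFrame) -> list[str]:
    """Apply the MFI cutoff rule to a bead table (columns allele/mfi/is_self)."""
    self_mfi = panel.loc[panel["is_self"], "mfi"]
    if len(self_mfi) < 2:
        raise ValueError("cutoff undefined: fewer than 2 self beads")
    cutoff = self_mfi.mean() + 3.0 * self_mfi.std(ddof=1)
    hits = panel[(~panel["is_self"]) & (panel["mfi"] > 100.0) & (panel["mfi"] > cutoff)]
    return sorted(hits["allele"])
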
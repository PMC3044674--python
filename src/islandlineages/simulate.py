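"""Forward Wright-Fisher simulator of a patrilocal multi-village island.

Each village holds a constant number of adults per discrete generation
(half men, half women).  Every offspring slot in a village draws its
father from that village with probability ``1 - male_migration`` (else
from a random other village) and its mother's natal village is another
village with probability ``female_migration`` — women move at marriage,
men mostly do not, which is the patrilocal residence pattern that
predicts strong between-village Y-chromosome structure and weak mtDNA
structure.

Sons inherit the father's patriline label, Y-SNP haplogroup and Y-STR
haplotype (stepwise +/-1 mutations per locus); all children inherit the
mother's mtDNA haplotype, represented as a variant set against the
packaged reference with Poisson mutation counts per lineage-generation:
HVS-1 transitions in nps 16090-16365 and synonymous coding transitions
restricted to sites that are silent on the packaged gene map, so that the
dating filters see exactly the simulated mutation classes.  An
infinite-sites approximation re-draws positions that would recur within
a lineage.

Genealogy bookkeeping mirrors a patrilineal kinship survey: each founding
patriline is an ancestral family (village + Roman numeral) and the
patriline branches alive a few generations before the present define the
integer-labelled extended families.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    HVS1_RHO,
    HVS1_SEQUENCED,
    IslandLineagesError,
    MtSample,
    MutationKind,
    StrProfile,
    Variant,
    YFILER_SINGLE_COPY_LOCI,
    _TRANSITION_PARTNER,
    GenealogyRecord,
    load_reference,
    synonymous_transition_sites,
    write_fasta,
    write_genealogy,
    write_mt_samples,
    write_str_profiles,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimOutput",
    "DemographicError",
    "YAMI_VILLAGES",
    "YAMI_Y_HAPLOGROUP_FREQS",
    "simulate",
    "emit_dataset",
]


class DemographicError(IslandLineagesError, RuntimeError):
    """A village ran out of men or women at some generation."""


#: The six villages of Orchid Island.
YAMI_VILLAGES = ("Imourud", "Iraralai", "Yayu", "Iratai", "Iranmilk", "Ivarinu")

#: Y-SNP haplogroup founding frequencies patterned on the Yami sample
#: (30 men): O1a1*-P203 50%, O1a*-M119 33.3%, O2a*-M95 10%, plus single
#: O2a1a-PK4 and O3a4* lineages.
YAMI_Y_HAPLOGROUP_FREQS: dict[str, float] = {
    "O1a*-M119": 0.333,
    "O1a1*-P203": 0.500,
    "O2a*-M95": 0.100,
    "O2a1a-PK4": 0.034,
    "O3a4*-GSP002611": 0.033,
}

_HVS1_TS_RATE = 25.0 / 20180.0  # one transition per 20,180 y, 25-y generations
_SYN_TS_RATE = 25.0 / 6764.0    # one synonymous substitution per 6,764 y


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults: six villages of 30 adults, 120 generations
    (~3,000 years), women marrying across villages half the time, men
    sedentary, a handful of founding lineages per village, and the
    calibration mutation rates."""

    n_villages: int = 6
    village_size: int = 30
    generations: int = 120
    female_migration: float = 0.5
    male_migration: float = 0.0
    mt_founders_per_village: int = 3
    y_founders_per_village: int = 2
    hvs1_rate: float = _HVS1_TS_RATE
    coding_syn_rate: float = _SYN_TS_RATE
    ystr_rate: float = 6.9e-4
    generation_years: float = 25.0
    y_haplogroup_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(YAMI_Y_HAPLOGROUP_FREQS)
    )
    extended_family_depth: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.female_migration <= 1.0 and 0.0 <= self.male_migration <= 1.0):
            raise ValueError("migration probabilities must lie in [0, 1]")
        if min(self.hvs1_rate, self.coding_syn_rate, self.ystr_rate) < 0:
            raise ValueError("mutation rates must be non-negative")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.village_size < 2 or self.n_villages < 1:
            raise ValueError("need at least one village of at least 2 adults")


@dataclass
class SimTruth:
    """Ground truth for oracle tests: founder age, founder haplotypes and
    each sampled individual's matriline/patriline."""

    founder_age_years: float
    mt_founder_haplotypes: dict[int, frozenset[Variant]]
    y_founder_haplotypes: dict[int, tuple[int, ...]]
    y_founder_haplogroups: dict[int, str]
    matriline_of: dict[str, int]
    patriline_of: dict[str, int]
    male_migration_events: int
    female_migration_events: int


@dataclass
class SimOutput:
    mt_samples: list[MtSample]
    str_profiles: list[StrProfile]
    genealogy: list[GenealogyRecord]
    villages: tuple[str, ...]
    truth: SimTruth
    config: SimConfig


def _roman(n: int) -> str:
    numerals = ["X", "IX", "V", "IV", "I"]
    values = [10, 9, 5, 4, 1]
    out = []
    for v, s in zip(values, numerals):
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


# internal per-individual records (tuples for speed):
# male   = (patriline, extfam, ystr, mt, matriline)
# female = (mt, matriline)


def _mutate_mt(
    mt: frozenset,
    n_hvs1: int,
    n_syn: int,
    rng: np.random.Generator,
    reference: str,
    syn_sites: tuple[int, ...],
) -> frozenset:
    variants = set(mt)
    for _ in range(n_hvs1):
        while True:
            pos = int(rng.integers(HVS1_RHO.start, HVS1_RHO.end + 1))
            v = Variant(pos, _TRANSITION_PARTNER[reference[pos - 1]], MutationKind.TRANSITION)
            if v not in variants:
                variants.add(v)
                break
    for _ in range(n_syn):
        while True:
            pos = int(syn_sites[rng.integers(len(syn_sites))])
            v = Variant(pos, _TRANSITION_PARTNER[reference[pos - 1]], MutationKind.TRANSITION)
            if v not in variants:
                variants.add(v)
                break
    return frozenset(variants)


def simulate(config: SimConfig = SimConfig()) -> SimOutput:
    """Run the forward simulation and return the present-day generation as
    pipeline inputs plus the true history."""
    rng = np.random.default_rng(config.seed)
    reference = load_reference()
    syn_sites = synonymous_transition_sites() if config.coding_syn_rate > 0 else (590,)
    n_v = config.n_villages
    villages = tuple(YAMI_VILLAGES[:n_v]) + tuple(
        f"Village{i + 1}" for i in range(len(YAMI_VILLAGES), n_v)
    )
    n_m = config.village_size // 2
    n_f = config.village_size - n_m
    n_str_slots = len(YFILER_SINGLE_COPY_LOCI) + 2  # both DYS385 copies mutate

    # Founders (generation 0).
    hap_names = sorted(config.y_haplogroup_freqs)
    hap_probs = np.asarray([config.y_haplogroup_freqs[h] for h in hap_names], dtype=float)
    hap_probs = hap_probs / hap_probs.sum()
    mt_founder_haplotypes: dict[int, frozenset] = {}
    y_founder_haplotypes: dict[int, tuple[int, ...]] = {}
    y_founder_haplogroups: dict[int, str] = {}
    patriline_village: dict[int, int] = {}
    males: list[list] = []
    females: list[list] = []
    for v in range(n_v):
        v_m, v_f = [], []
        for k in range(config.y_founders_per_village):
            pid = v * config.y_founders_per_village + k
            patriline_village[pid] = v
            y_founder_haplogroups[pid] = hap_names[rng.choice(len(hap_names), p=hap_probs)]
            y_founder_haplotypes[pid] = tuple(int(x) for x in rng.integers(12, 20, n_str_slots))
        for k in range(config.mt_founders_per_village):
            mid = v * config.mt_founders_per_village + k
            n_motif = int(rng.integers(2, 5))
            pos = rng.choice(
                np.arange(HVS1_SEQUENCED.start, HVS1_SEQUENCED.end + 1), n_motif, replace=False
            )
            mt_founder_haplotypes[mid] = frozenset(
                Variant(int(p), _TRANSITION_PARTNER[reference[int(p) - 1]], MutationKind.TRANSITION)
                for p in pos
            )
        for i in range(n_m):
            pid = v * config.y_founders_per_village + i % config.y_founders_per_village
            mid = v * config.mt_founders_per_village + i % config.mt_founders_per_village
            v_m.append([pid, -1, y_founder_haplotypes[pid], mt_founder_haplotypes[mid], mid])
        for i in range(n_f):
            mid = v * config.mt_founders_per_village + i % config.mt_founders_per_village
            v_f.append([mt_founder_haplotypes[mid], mid])
        males.append(v_m)
        females.append(v_f)

    ext_assign_gen = max(0, config.generations - config.extended_family_depth)
    next_extfam = 1
    male_migrations = female_migrations = 0
    if ext_assign_gen == 0:
        for v in range(n_v):
            for m in males[v]:
                m[1] = next_extfam
                next_extfam += 1

    for gen in range(1, config.generations + 1):
        new_males: list[list] = []
        new_females: list[list] = []
        for v in range(n_v):
            n_children = n_m + n_f
            father_other = rng.random(n_children) < config.male_migration
            mother_other = rng.random(n_children) < config.female_migration
            v_m, v_f = [], []
            for c in range(n_children):
                fv = v
                if father_other[c] and n_v > 1:
                    fv = int(rng.integers(n_v - 1))
                    fv += fv >= v
                    male_migrations += 1
                mv = v
                if mother_other[c] and n_v > 1:
                    mv = int(rng.integers(n_v - 1))
                    mv += mv >= v
                    female_migrations += 1
                if not males[fv]:
                    raise DemographicError(f"no men in {villages[fv]} at generation {gen}")
                if not females[mv]:
                    raise DemographicError(f"no women in {villages[mv]} at generation {gen}")
                father = males[fv][int(rng.integers(len(males[fv])))]
                mother = females[mv][int(rng.integers(len(females[mv])))]

                mt = mother[0]
                n_h = rng.poisson(config.hvs1_rate) if config.hvs1_rate > 0 else 0
                n_s = rng.poisson(config.coding_syn_rate) if config.coding_syn_rate > 0 else 0
                if n_h or n_s:
                    mt = _mutate_mt(mt, int(n_h), int(n_s), rng, reference, syn_sites)

                if c < n_m:  # son
                    ystr = father[2]
                    n_y = rng.binomial(n_str_slots, config.ystr_rate) if config.ystr_rate > 0 else 0
                    if n_y:
                        slots = rng.choice(n_str_slots, int(n_y), replace=False)
                        ystr = list(ystr)
                        for s in slots:
                            step = 1 if rng.random() < 0.5 else -1
                            ystr[int(s)] = max(1, ystr[int(s)] + step)
                        ystr = tuple(ystr)
                    v_m.append([father[0], father[1], ystr, mt, mother[1]])
                else:
                    v_f.append([mt, mother[1]])
            new_males.append(v_m)
            new_females.append(v_f)
        males, females = new_males, new_females
        if gen == ext_assign_gen:
            for v in range(n_v):
                for m in males[v]:
                    m[1] = next_extfam
                    next_extfam += 1

    # Package the present-day generation.
    mt_samples: list[MtSample] = []
    str_profiles: list[StrProfile] = []
    genealogy: list[GenealogyRecord] = []
    matriline_of: dict[str, int] = {}
    patriline_of: dict[str, int] = {}
    counter = 0
    for v in range(n_v):
        vname = villages[v]
        for sex, pool in (("M", males[v]), ("F", females[v])):
            for ind in pool:
                counter += 1
                sid = f"Y{sex}{counter:04d}"
                if sex == "M":
                    pid, extfam, ystr, mt, mid = ind
                    repeats = dict(zip(YFILER_SINGLE_COPY_LOCI, ystr[:-2]))
                    str_profiles.append(
                        StrProfile(sid, y_founder_haplogroups[pid], repeats,
                                   (ystr[-2], ystr[-1]), vname)
                    )
                    anc = f"{villages[patriline_village[pid]]}-{_roman(pid % config.y_founders_per_village + 1)}"
                    genealogy.append(GenealogyRecord(sid, vname, anc, extfam))
                    patriline_of[sid] = pid
                else:
                    mt, mid = ind
                mt_samples.append(MtSample(sid, vname, mt))
                matriline_of[sid] = mid

    truth = SimTruth(
        founder_age_years=config.generations * config.generation_years,
        mt_founder_haplotypes=mt_founder_haplotypes,
        y_founder_haplotypes=y_founder_haplotypes,
        y_founder_haplogroups=y_founder_haplogroups,
        matriline_of=matriline_of,
        patriline_of=patriline_of,
        male_migration_events=male_migrations,
        female_migration_events=female_migrations,
    )
    return SimOutput(mt_samples, str_profiles, genealogy, villages, truth, config)


def emit_dataset(sim: SimOutput, out_dir) -> dict[str, Path]:
    """Write the simulated collections in the dialects the readers parse
    (round-trip identity), plus an HVS-1 FASTA of the mtDNA haplotypes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mt_samples": out / "mt_samples.tsv",
        "str_profiles": out / "str_profiles.tsv",
        "genealogy": out / "genealogy.tsv",
        "hvs1_fasta": out / "hvs1_sequences.fa",
    }
    write_mt_samples(sim.mt_samples, paths["mt_samples"])
    write_str_profiles(sim.str_profiles, paths["str_profiles"])
    write_genealogy(sim.genealogy, paths["genealogy"])

    reference = load_reference()
    start, end = HVS1_SEQUENCED.start, HVS1_SEQUENCED.end
    sequences = {}
    for s in sim.mt_samples:
        seq = list(reference[start - 1 : end])
        for v in s.variants:
            if v.kind in (MutationKind.TRANSITION, MutationKind.TRANSVERSION) and start <= v.position <= end:
                seq[v.position - start] = v.derived
        sequences[s.sample_id] = "".join(seq)
    write_fasta(sequences, paths["hvs1_fasta"])
    return paths
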
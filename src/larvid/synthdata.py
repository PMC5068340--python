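"""Seeded generator of taxonomies, reference databases and query sets.

The generator emulates the statistical structure a desk-scale barcoding
study has to cope with, each knob mapping to a failure mode of real
reference databases:

* **incompleteness** — each database holds each species only with some
  probability, so queries of missing species fall back to shallower ranks
  or to the other database;
* **conflicting labels** — a fraction of second-database records are
  relabelled to a congener, producing between-database discrepancies;
* **ambiguous duplicates** — a fraction of second-database sequences are
  copied verbatim under a second congeneric species name, producing
  unresolvable best-hit ties;
* **divergence** — queries are copies of a species' reference mutated under
  a two-parameter (transition/transversion) substitution process;
* **pseudogene contamination** — a fraction of queries receive a single
  1-bp deletion, frameshifting the downstream read and (with overwhelming
  probability) introducing internal stop codons.

Reference sequences are built codon-wise from the 60 sense codons of the
vertebrate mitochondrial code, so every reference translates cleanly in
frame 0, and species are kept ≤95% pairwise identical by rejection so the
97% identity cutoff separates them.

Every output is deterministic given the config seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .seqio_qc import QueryRecord, ReferenceRecord, write_fasta
from .taxonomy import Lineage, Taxonomy

_BASES = "ACGT"
#: stop codons of the vertebrate mitochondrial code (NCBI table 2)
STOP_CODONS = ("TAA", "TAG", "AGA", "AGG")
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product(_BASES, repeat=3) if "".join(c) not in STOP_CODONS
)
assert len(SENSE_CODONS) == 60

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

#: maximum raw identity allowed between two reference species
MAX_INTERSPECIES_IDENTITY = 0.95

#: pseudogene deletions avoid this many nt at each amplicon end: a
#: frameshift close to an end leaves too few shifted codons to hit a stop
#: (each shifted codon is a stop w.p. ~0.06), a documented blind spot of
#: translation screens that the generator's pseudogenes — meant to be
#: detectable contamination — deliberately stay clear of
PSEUDOGENE_END_MARGIN = 150

# fixed offsets fanning one config seed out into per-stage streams
_SEED_TAXONOMY, _SEED_REFS, _SEED_DBS, _SEED_QUERIES, _SEED_STATIONS = 11, 23, 37, 53, 71


def _stage_seed(seed: int, offset: int) -> int:
    return (seed * 1_000_003 + offset) % (2**31)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one simulated survey.

    Defaults mirror a desk-scale larval survey: 44 species, 237 queries of
    630 nt (a typical edited COI amplicon length), eight stations, complete
    concordant databases, 0.5% query-to-reference divergence with a
    transition/transversion ratio of 4, and no pseudogene contamination.
    """

    n_species: int = 44
    n_queries: int = 237
    seq_length: int = 630
    completeness_db1: float = 1.0
    completeness_db2: float = 1.0
    conflict_rate: float = 0.0
    dup_rate: float = 0.0
    divergence: float = 0.005
    kappa: float = 4.0
    pseudogene_fraction: float = 0.0
    n_stations: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "completeness_db1",
            "completeness_db2",
            "conflict_rate",
            "dup_rate",
            "pseudogene_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seq_length < 60 or self.seq_length % 3:
            raise ValueError("seq_length must be ≥60 and a multiple of 3")
        if self.divergence < 0:
            raise ValueError("divergence must be ≥ 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        for name in ("n_species", "n_queries", "n_stations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


@dataclass
class QueryTruth:
    species: str
    lineage: Lineage
    station: str
    is_pseudogene: bool


@dataclass
class GroundTruth:
    """Record of every manipulation the generator performed."""

    queries: dict[str, QueryTruth] = field(default_factory=dict)
    db1_species: frozenset[str] = frozenset()
    db2_species: frozenset[str] = frozenset()
    #: db2 records whose species label was swapped: true species -> label used
    conflicts: dict[str, str] = field(default_factory=dict)
    #: db2 sequences copied under a second name: source species -> extra label
    duplicates: dict[str, str] = field(default_factory=dict)

    def add_query(self, qid: str, truth: QueryTruth) -> None:
        if qid in self.queries:
            raise ValueError(f"query id {qid!r} recorded twice")
        self.queries[qid] = truth

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "query_id": qid,
                "species": t.species,
                "order": t.lineage.order,
                "family": t.lineage.family,
                "genus": t.lineage.genus,
                "station": t.station,
                "is_pseudogene": t.is_pseudogene,
                "in_db1": t.species in self.db1_species,
                "in_db2": t.species in self.db2_species,
                "db2_conflict_label": self.conflicts.get(t.species, ""),
                "db2_duplicate_label": self.duplicates.get(t.species, ""),
            }
            for qid, t in self.queries.items()
        ]
        return pd.DataFrame(rows)


def generate_taxonomy(
    n_orders: int,
    n_families_per_order: int,
    n_genera_per_family: int,
    n_species_per_genus: int,
    seed: int = 0,
) -> Taxonomy:
    """A fully balanced synthetic taxonomy with systematic names.

    Names avoid underscores and newick metacharacters; species are binomial
    ("Gen003 sp2") so genus membership is visible at a glance.
    """
    counts = (n_orders, n_families_per_order, n_genera_per_family, n_species_per_genus)
    if any(c < 1 for c in counts):
        raise ValueError(f"all counts must be ≥ 1, got {counts}")
    del seed  # naming is systematic; accepted for interface symmetry
    lineages = []
    fam_i = gen_i = 0
    for o in range(n_orders):
        order = f"Ord{o + 1:02d}"
        for _f in range(n_families_per_order):
            fam_i += 1
            family = f"Fam{fam_i:03d}"
            for _g in range(n_genera_per_family):
                gen_i += 1
                genus = f"Gen{gen_i:03d}"
                for s in range(n_species_per_genus):
                    lineages.append(Lineage(order, family, genus, f"{genus} sp{s + 1}"))
    return Taxonomy(tuple(lineages))


def taxonomy_for_n_species(n_species: int, seed: int = 0) -> Taxonomy:
    """A taxonomy of exactly ``n_species``: 2 species/genus, 2 genera/family,
    2 families/order (last groups possibly smaller)."""
    if n_species < 1:
        raise ValueError("n_species must be ≥ 1")
    n_orders = -(-n_species // 8)
    full = generate_taxonomy(n_orders, 2, 2, 2, seed=seed)
    return Taxonomy(full.entries[:n_species])


#: expected substitutions/site added on the branch into each rank's ancestor
BRANCH_DIVERGENCE = {"order": 0.06, "family": 0.05, "genus": 0.04, "species": 0.03}


def _draw_root(rng: np.random.Generator, seq_length: int) -> str:
    codon_idx = rng.integers(0, len(SENSE_CODONS), size=seq_length // 3)
    return "".join(SENSE_CODONS[i] for i in codon_idx)


def _mutate_stopfree(
    seq: str, divergence: float, kappa: float, rng: np.random.Generator
) -> str:
    """Two-parameter substitution at ``round(divergence*len)`` distinct sites
    that never creates a frame-0 stop codon (falls back to the alternative
    bases when the drawn one would)."""
    n_sub = round(divergence * len(seq))
    if n_sub == 0:
        return seq
    out = list(seq)
    p_ts = kappa / (kappa + 2.0)
    for pos in rng.choice(len(seq), size=n_sub, replace=False):
        base = out[pos]
        if rng.random() < p_ts:
            first = _TRANSITION[base]
        else:
            first = _TRANSVERSIONS[base][rng.integers(0, 2)]
        others = [b for b in _BASES if b not in (base, first)]
        rng.shuffle(others)
        start = 3 * (pos // 3)
        codon = out[start : start + 3]
        for cand in [first, *others]:
            codon[pos % 3 - 3] = cand
            if "".join(codon) not in STOP_CODONS:
                out[pos] = cand
                break
    return "".join(out)


def generate_reference_seqs(
    taxonomy: Taxonomy,
    seq_length: int = 630,
    seed: int = 0,
    kappa: float = 4.0,
    branch_divergence: Optional[Mapping[str, float]] = None,
) -> dict[str, str]:
    """One stop-free reference per species, evolved down the taxonomy.

    A root sequence is drawn codon-wise from the 60 sense codons of the
    vertebrate mitochondrial code; ancestors of each order, family and genus
    and finally each species accumulate stop-free substitutions along their
    branches, so congeners are more alike than confamilials and distances
    stay below K2P saturation.  Any species within 95% raw identity of an
    already generated species is redrawn from its genus ancestor.
    """
    if seq_length % 3:
        raise ValueError("seq_length must be a multiple of 3")
    rng = np.random.default_rng(seed)
    div = dict(BRANCH_DIVERGENCE, **(branch_divergence or {}))
    root = _draw_root(rng, seq_length)
    ancestors: dict[tuple[str, ...], str] = {}
    refs: dict[str, str] = {}
    done: list[np.ndarray] = []  # byte arrays for fast identity checks
    for lin in taxonomy:
        parent = root
        for rank in ("order", "family", "genus"):
            key = lin.truncate(rank)
            if key not in ancestors:
                ancestors[key] = _mutate_stopfree(parent, div[rank], kappa, rng)
            parent = ancestors[key]
        for _attempt in range(100):
            seq = _mutate_stopfree(parent, div["species"], kappa, rng)
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            if all(
                (arr == other).mean() <= MAX_INTERSPECIES_IDENTITY for other in done
            ):
                break
        else:
            raise RuntimeError(
                f"could not separate {lin.species} from existing species"
            )
        refs[lin.species] = seq
        done.append(arr)
    return refs


def mutate_sequence(seq: str, divergence: float, kappa: float = 4.0, seed: int = 0) -> str:
    """Substitute ``round(divergence * len(seq))`` distinct uniform positions.

    Each substitution is a transition with probability kappa/(kappa+2) and
    otherwise one of the two transversions, equiprobably.  Length is
    preserved and divergence 0 returns the input unchanged.
    """
    if divergence < 0:
        raise ValueError("divergence must be ≥ 0")
    n_sub = round(divergence * len(seq))
    if n_sub == 0:
        return seq
    if n_sub > len(seq):
        raise ValueError("divergence implies more substitutions than sites")
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    p_ts = kappa / (kappa + 2.0)
    for pos in positions:
        base = out[pos]
        if rng.random() < p_ts:
            out[pos] = _TRANSITION[base]
        else:
            out[pos] = _TRANSVERSIONS[base][rng.integers(0, 2)]
    return "".join(out)


def _select_fraction(rng: np.random.Generator, items: Sequence[str], rate: float) -> list[str]:
    k = round(rate * len(items))
    if k == 0:
        return []
    return list(rng.choice(np.asarray(items, dtype=object), size=k, replace=False))


def build_databases(
    refs: Mapping[str, str], taxonomy: Taxonomy, config: SynthConfig
) -> tuple[list[ReferenceRecord], list[ReferenceRecord], GroundTruth]:
    """Sample two reference databases from the species pool and inject the
    configured label conflicts and ambiguous duplicates into the second."""
    if not refs:
        raise ValueError("refs is empty")
    rng = np.random.default_rng(_stage_seed(config.seed, _SEED_DBS))
    species = [lin.species for lin in taxonomy if lin.species in refs]

    present1 = [s for s in species if rng.random() < config.completeness_db1]
    present2 = [s for s in species if rng.random() < config.completeness_db2]

    truth = GroundTruth(
        db1_species=frozenset(present1), db2_species=frozenset(present2)
    )

    db1 = [
        ReferenceRecord(f"DB1-R{i + 1:04d}", refs[s], taxonomy.lineage_of(s))
        for i, s in enumerate(present1)
    ]

    # db2 manipulations apply only to species that actually have a congener
    eligible = [s for s in present2 if taxonomy.congeners(s)]
    conflicted = set(_select_fraction(rng, eligible, config.conflict_rate))
    duplicated = set(_select_fraction(rng, eligible, config.dup_rate))

    db2: list[ReferenceRecord] = []
    rid = 0
    for s in present2:
        rid += 1
        label = s
        if s in conflicted:
            congeners = taxonomy.congeners(s)
            label = congeners[rng.integers(0, len(congeners))]
            truth.conflicts[s] = label
        db2.append(ReferenceRecord(f"DB2-R{rid:04d}", refs[s], taxonomy.lineage_of(label)))
        if s in duplicated:
            congeners = [c for c in taxonomy.congeners(s) if c != label]
            if not congeners:
                congeners = list(taxonomy.congeners(s))
            dup_label = congeners[rng.integers(0, len(congeners))]
            rid += 1
            db2.append(
                ReferenceRecord(f"DB2-R{rid:04d}", refs[s], taxonomy.lineage_of(dup_label))
            )
            truth.duplicates[s] = dup_label
    return db1, db2, truth


def generate_queries(
    refs: Mapping[str, str],
    taxonomy: Taxonomy,
    truth: GroundTruth,
    config: SynthConfig,
) -> list[QueryRecord]:
    """Mutated copies of randomly chosen species' references, assigned to
    stations; a ``pseudogene_fraction`` subset gets one 1-bp deletion.

    Substitutions are stop-free (a genuine amplicon comes from a functional
    gene, so it still translates cleanly); only the pseudogene deletion may
    disrupt the reading frame.  The deletion position is uniform over the
    amplicon interior (:data:`PSEUDOGENE_END_MARGIN` nt clear of each end),
    so the frameshift scrambles enough codons to be detectable."""
    if not refs:
        raise ValueError("refs is empty")
    rng = np.random.default_rng(_stage_seed(config.seed, _SEED_QUERIES))
    species = [lin.species for lin in taxonomy if lin.species in refs]
    n = config.n_queries
    n_pg = round(config.pseudogene_fraction * n)
    pg_idx = set(rng.choice(n, size=n_pg, replace=False)) if n_pg else set()

    queries: list[QueryRecord] = []
    for i in range(n):
        sp = species[rng.integers(0, len(species))]
        seq = _mutate_stopfree(refs[sp], config.divergence, config.kappa, rng)
        is_pg = i in pg_idx
        if is_pg:
            margin = min(PSEUDOGENE_END_MARGIN, len(seq) // 3)
            pos = int(rng.integers(margin, len(seq) - margin))
            seq = seq[:pos] + seq[pos + 1 :]
        station = f"St{int(rng.integers(1, config.n_stations + 1))}"
        qid = f"Q{i + 1:04d}"
        queries.append(QueryRecord(qid, seq, station=station))
        truth.add_query(qid, QueryTruth(sp, taxonomy.lineage_of(sp), station, is_pg))
    return queries


@dataclass
class StationRecord:
    """One sampling station: id, latitude and filtered water volume."""

    station: str
    latitude: float
    volume_m3: float

    def __post_init__(self) -> None:
        if self.volume_m3 <= 0:
            raise ValueError(f"station {self.station}: volume must be > 0")


def generate_stations(config: SynthConfig) -> list[StationRecord]:
    """Stations on a 37°N → 2°S latitudinal transect with plausible Bongo
    filtered volumes (200–600 m³, seeded)."""
    rng = np.random.default_rng(_stage_seed(config.seed, _SEED_STATIONS))
    lats = np.linspace(37.0, -2.0, config.n_stations)
    return [
        StationRecord(f"St{i + 1}", round(float(lat), 3), round(float(rng.uniform(200, 600)), 1))
        for i, lat in enumerate(lats)
    ]


@dataclass
class SimulationResult:
    config: SynthConfig
    taxonomy: Taxonomy
    refs: dict[str, str]
    db1: list[ReferenceRecord]
    db2: list[ReferenceRecord]
    queries: list[QueryRecord]
    truth: GroundTruth
    stations: list[StationRecord]


def simulate(config: SynthConfig, outdir: Optional[Path] = None) -> SimulationResult:
    """Run the whole generator; optionally write the standard file set
    (db1/db2/queries FASTA, taxonomy/truth/stations TSV) under ``outdir``."""
    taxonomy = taxonomy_for_n_species(
        config.n_species, seed=_stage_seed(config.seed, _SEED_TAXONOMY)
    )
    refs = generate_reference_seqs(
        taxonomy, config.seq_length, seed=_stage_seed(config.seed, _SEED_REFS)
    )
    db1, db2, truth = build_databases(refs, taxonomy, config)
    queries = generate_queries(refs, taxonomy, truth, config)
    stations = generate_stations(config)
    result = SimulationResult(config, taxonomy, refs, db1, db2, queries, truth, stations)
    if outdir is not None:
        write_simulation(result, Path(outdir))
    return result


def write_simulation(result: SimulationResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.db1, outdir / "db1.fasta")
    write_fasta(result.db2, outdir / "db2.fasta")
    write_fasta(result.queries, outdir / "queries.fasta")
    result.taxonomy.write_tsv(outdir / "taxonomy.tsv")
    result.truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"station": s.station, "latitude": s.latitude, "volume_m3": s.volume_m3}
            for s in result.stations
        ]
    ).to_csv(outdir / "stations.tsv", sep="\t", index=False)
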
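"""Synthetic annotation universes and measurement tables for testing.

The generator emulates the structural quirks of real domain annotation data:

* several member databases, optionally *redundancy partners* that carry the
  same gene memberships under fresh feature accessions (as the partially
  redundant InterPro member databases do);
* genes with a variable number of transcripts whose domain composition
  differs (a feature may sit on only some transcripts of its gene);
* a configurable fraction of genes with zero annotations, which stay in the
  background population;
* measurement values drawn from a background normal, with selected "planted"
  features whose member genes draw from a location-shifted normal.

It also packages a small worked example: seven plexin genes with their
published polyploidy RNAi z-scores, a plexin cytoplasmic RasGAP domain
grouping, and a synthetic screen background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .annotations import AnnotationStore, ColumnSpec, FeatureRecord, IdentifierMap
from .enrichment import MeasurementTable
from .errors import ConfigurationError

__all__ = [
    "DatabaseSpec",
    "PlantedFeature",
    "SimulationSpec",
    "SimulatedData",
    "simulate",
    "write_fixture",
    "plexin_fixture",
    "PLEXIN_ZSCORES",
    "RASGAP_PLEXINS",
]


@dataclass(frozen=True)
class DatabaseSpec:
    """One member database to generate.  A ``redundancy_partner`` clones the
    named database's gene memberships under fresh feature accessions."""

    name: str
    n_features: int = 50
    redundancy_partner: str | None = None


@dataclass(frozen=True)
class PlantedFeature:
    """A feature whose member genes draw values from a shifted normal."""

    database: str
    feature_index: int
    shift: float
    sd: float | None = None  # defaults to the background sd


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic dataset; ``seed`` fixes all randomness.

    Defaults describe a modest genome-scale screen: 1000 genes, 1-3
    transcripts each, one database of 50 domain features of 5-25 genes
    (domain families are typically small), 10% of genes unannotated, and
    standard-normal background values (z-score scale).
    """

    n_genes: int = 1000
    transcripts_per_gene: tuple[int, int] = (1, 3)
    databases: tuple[DatabaseSpec, ...] = (DatabaseSpec("dbA", 50),)
    feature_size: tuple[int, int] = (5, 25)
    planted: tuple[PlantedFeature, ...] = ()
    background: tuple[float, float] = (0.0, 1.0)
    unannotated_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ConfigurationError("n_genes must be >= 2")
        if not 1 <= self.transcripts_per_gene[0] <= self.transcripts_per_gene[1]:
            raise ConfigurationError("transcripts_per_gene must be 1 <= lo <= hi")
        if not 1 <= self.feature_size[0] <= self.feature_size[1]:
            raise ConfigurationError("feature_size must be 1 <= lo <= hi")
        if not 0.0 <= self.unannotated_fraction < 1.0:
            raise ConfigurationError("unannotated_fraction must lie in [0, 1)")
        if self.background[1] <= 0:
            raise ConfigurationError("background sd must be positive")
        names = [db.name for db in self.databases]
        if len(set(names)) != len(names):
            raise ConfigurationError("database names must be unique")
        for db in self.databases:
            if db.n_features < 1:
                raise ConfigurationError(f"{db.name}: n_features must be >= 1")
            if db.redundancy_partner is not None and (
                db.redundancy_partner not in names
                or db.redundancy_partner == db.name
            ):
                raise ConfigurationError(
                    f"{db.name}: redundancy_partner must name another database"
                )
        n_annotated = self.n_genes - int(round(self.n_genes * self.unannotated_fraction))
        if self.feature_size[1] > n_annotated:
            raise ConfigurationError(
                f"feature_size upper bound {self.feature_size[1]} exceeds the "
                f"{n_annotated} annotated genes"
            )
        by_db = {db.name: db for db in self.databases}
        for pf in self.planted:
            if pf.database not in by_db:
                raise ConfigurationError(f"planted feature in unknown database {pf.database}")
            if not 0 <= pf.feature_index < by_db[pf.database].n_features:
                raise ConfigurationError(
                    f"planted feature index {pf.feature_index} out of range for "
                    f"{pf.database}"
                )
            if pf.sd is not None and pf.sd <= 0:
                raise ConfigurationError("planted sd must be positive")

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationSpec":
        """Build a spec from a plain dict (JSON/YAML spec file)."""
        data = dict(raw)
        if "databases" in data:
            data["databases"] = tuple(
                DatabaseSpec(**db) if isinstance(db, dict) else DatabaseSpec(db)
                for db in data["databases"]
            )
        if "planted" in data:
            data["planted"] = tuple(
                PlantedFeature(**pf) for pf in data["planted"]
            )
        for key in ("transcripts_per_gene", "feature_size", "background"):
            if key in data:
                data[key] = tuple(data[key])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigurationError(f"invalid simulation spec: {exc}") from None

    def to_dict(self) -> dict:
        return asdict(self)


class SimulatedData(NamedTuple):
    store: AnnotationStore
    idmap: IdentifierMap
    measurements: MeasurementTable
    truth: tuple[tuple[str, str], ...]  # (database, feature_id) of planted sets


def simulate(spec: SimulationSpec) -> SimulatedData:
    """Generate a synthetic dataset; deterministic for a given spec.

    Annotation topology and measurement values come from independent streams
    of the seed, so changing the database layout (e.g. adding a redundancy
    partner) never perturbs the measurement vector.
    """
    annot_seed, value_seed = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(annot_seed)
    rng_values = np.random.default_rng(value_seed)

    genes = [f"ENSG{i:06d}" for i in range(spec.n_genes)]
    symbols = [f"GENE{i:05d}" for i in range(spec.n_genes)]
    lo, hi = spec.transcripts_per_gene
    n_tx = rng.integers(lo, hi + 1, size=spec.n_genes)
    gene_tx = {
        g: [f"{g}T{k}" for k in range(n_tx[i])] for i, g in enumerate(genes)
    }

    n_unannotated = int(round(spec.n_genes * spec.unannotated_fraction))
    unannotated = set(
        rng.choice(spec.n_genes, size=n_unannotated, replace=False).tolist()
    )
    annotated_idx = np.array(
        [i for i in range(spec.n_genes) if i not in unannotated]
    )

    # gene memberships per database; redundancy partners copy their source
    memberships: dict[str, list[np.ndarray]] = {}
    for db in spec.databases:
        if db.redundancy_partner is not None:
            continue
        sizes = rng.integers(
            spec.feature_size[0], spec.feature_size[1] + 1, size=db.n_features
        )
        memberships[db.name] = [
            np.sort(rng.choice(annotated_idx, size=s, replace=False))
            for s in sizes
        ]
    for db in spec.databases:
        if db.redundancy_partner is not None:
            source = memberships[db.redundancy_partner]
            memberships[db.name] = [m.copy() for m in source[: db.n_features]]
            if db.n_features > len(source):
                extra = rng.integers(
                    spec.feature_size[0],
                    spec.feature_size[1] + 1,
                    size=db.n_features - len(source),
                )
                memberships[db.name] += [
                    np.sort(rng.choice(annotated_idx, size=s, replace=False))
                    for s in extra
                ]

    databases: dict[str, dict[str, FeatureRecord]] = {}
    for db in spec.databases:
        feats: dict[str, FeatureRecord] = {}
        partner = db.redundancy_partner
        for k, members in enumerate(memberships[db.name]):
            fid = f"{db.name}:F{k:04d}"
            transcripts: set[str] = set()
            for gi in members:
                txs = gene_tx[genes[gi]]
                take = int(rng.integers(1, len(txs) + 1))
                chosen = rng.choice(len(txs), size=take, replace=False)
                transcripts.update(txs[c] for c in chosen)
            # partners share the umbrella accession with their source feature,
            # mirroring how one InterPro entry groups equivalent member-db signatures
            umbrella_owner = partner if partner is not None and k < len(
                memberships[partner]
            ) else db.name
            feats[fid] = FeatureRecord(
                feature_id=fid,
                database_name=db.name,
                description=f"synthetic domain family {k} ({db.name})",
                umbrella_id=f"IPRS{umbrella_owner}{k:04d}",
                transcript_ids=frozenset(transcripts),
            )
        databases[db.name] = feats

    # the store's topology covers exactly the transcripts that carry >=1
    # feature, matching what a flat annotation export can represent
    tx_used: dict[str, set[str]] = {}
    tx_gene = {t: g for g, ts in gene_tx.items() for t in ts}
    for feats in databases.values():
        for rec in feats.values():
            for t in rec.transcript_ids:
                tx_used.setdefault(tx_gene[t], set()).add(t)
    store = AnnotationStore(
        databases=databases,
        gene_to_transcripts={g: frozenset(ts) for g, ts in tx_used.items()},
    )
    store.validate()

    idmap = IdentifierMap(
        entries=frozenset(zip(symbols, genes)), id_level="gene"
    )

    mean, sd = spec.background
    values = rng_values.normal(mean, sd, size=spec.n_genes)
    planted_of: dict[int, PlantedFeature] = {}
    truth: list[tuple[str, str]] = []
    for pf in spec.planted:
        fid = f"{pf.database}:F{pf.feature_index:04d}"
        truth.append((pf.database, fid))
        for gi in memberships[pf.database][pf.feature_index]:
            planted_of.setdefault(int(gi), pf)  # first planted membership wins
    for gi, pf in sorted(planted_of.items()):
        values[gi] = rng_values.normal(
            mean + pf.shift, pf.sd if pf.sd is not None else sd
        )

    measurements = MeasurementTable(identifiers=tuple(symbols), values=values)
    return SimulatedData(store, idmap, measurements, tuple(truth))


def write_fixture(data: SimulatedData, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset as the TSV dialects the loaders consume.

    Emits annotations.tsv, measurements.tsv, synonyms.tsv and truth.tsv and
    returns their paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotations": out / "annotations.tsv",
        "measurements": out / "measurements.tsv",
        "synonyms": out / "synonyms.tsv",
        "truth": out / "truth.tsv",
    }
    data.store.to_frame(ColumnSpec()).to_csv(
        paths["annotations"], sep="\t", index=False
    )
    pd.DataFrame(
        {"identifier": data.measurements.identifiers, "value": data.measurements.values}
    ).to_csv(paths["measurements"], sep="\t", index=False)
    pd.DataFrame(
        sorted(data.idmap.entries), columns=["user_id", "ensembl_id"]
    ).assign(level=data.idmap.id_level).to_csv(
        paths["synonyms"], sep="\t", index=False
    )
    pd.DataFrame(list(data.truth), columns=["database", "feature_id"]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    return paths


# ---------------------------------------------------------------------------
# Worked example: plexin polyploidy z-scores
# ---------------------------------------------------------------------------

#: Published polyploidy RNAi z-scores of the seven plexins assayed in the
#: genome-wide cell cycle progression screen, keyed by gene symbol.
PLEXIN_ZSCORES: dict[str, tuple[str, float]] = {
    "PLXNA1": ("ENSG00000114554", 13.15),
    "PLXNA2": ("ENSG00000076356", 4.05),
    "PLXNA3": ("ENSG00000130827", 2.72),
    "PLXNB1": ("ENSG00000164050", 3.14),
    "PLXNB2": ("ENSG00000196576", 3.33),
    "PLXND1": ("ENSG00000004399", 1.45),
    "PLXNC1": ("ENSG00000136040", 0.32),
}

#: Plexins carrying the cytoplasmic RasGAP domain: all of the assayed family
#: except PLXNC1, whose cytoplasmic portion lacks the split GAP homology.
#: Configurable fixture metadata, not a claim about any annotation release.
RASGAP_PLEXINS: tuple[str, ...] = (
    "PLXNA1",
    "PLXNA2",
    "PLXNA3",
    "PLXNB1",
    "PLXNB2",
    "PLXND1",
)

RASGAP_FEATURE_ID = "SYN:RASGAP_PLEXIN"
PLEXIN_FAMILY_FEATURE_ID = "SYN:PLEXIN_FAMILY"
PLEXIN_DATABASE = "SYNTH"


def plexin_fixture(
    n_background: int = 500,
    *,
    n_background_features: int = 10,
    background: tuple[float, float] = (0.0, 1.0),
    rasgap_members: tuple[str, ...] = RASGAP_PLEXINS,
    seed: int = 0,
) -> tuple[AnnotationStore, MeasurementTable]:
    """Worked-example dataset: the seven plexin z-scores in a synthetic screen.

    The measurement table holds the seven plexins (keyed by Ensembl gene id)
    with their published polyploidy z-scores plus ``n_background`` synthetic
    genes drawn from ``background``.  The store defines, under a synthetic
    member database with placeholder accessions, a cytoplasmic-RasGAP-domain
    feature over ``rasgap_members`` (default: the six RasGAP plexins, PLXNC1
    excluded), an alternate all-plexins grouping, and background features.

    The genome-wide screen behind the published analysis is not packaged, so
    this fixture supports smoke tests, median and rho checks — not a
    reproduction of the published enrichment p-value.
    """
    rng = np.random.default_rng(seed)
    bg_genes = [f"ENSGSYN{i:05d}" for i in range(n_background)]

    gene_tx = {eid: (f"{eid}T0",) for _, (eid, _) in PLEXIN_ZSCORES.items()}
    gene_tx.update({g: (f"{g}T0",) for g in bg_genes})

    def record(fid: str, desc: str, umbrella: str, gene_ids) -> FeatureRecord:
        return FeatureRecord(
            feature_id=fid,
            database_name=PLEXIN_DATABASE,
            description=desc,
            umbrella_id=umbrella,
            transcript_ids=frozenset(gene_tx[g][0] for g in gene_ids),
        )

    feats = {
        RASGAP_FEATURE_ID: record(
            RASGAP_FEATURE_ID,
            "Plexin cytoplasmic RasGAP domain (synthetic placeholder accession)",
            "IPRSYN0001",
            [PLEXIN_ZSCORES[s][0] for s in rasgap_members],
        ),
        PLEXIN_FAMILY_FEATURE_ID: record(
            PLEXIN_FAMILY_FEATURE_ID,
            "Plexin family, all assayed members (synthetic placeholder accession)",
            "IPRSYN0002",
            [eid for eid, _ in PLEXIN_ZSCORES.values()],
        ),
    }
    if n_background_features:
        size = max(2, min(20, n_background // max(n_background_features, 1)))
        for k in range(n_background_features):
            members = rng.choice(n_background, size=size, replace=False)
            fid = f"SYN:BG{k:03d}"
            feats[fid] = record(
                fid,
                f"synthetic background domain family {k}",
                f"IPRSYNB{k:03d}",
                [bg_genes[m] for m in members],
            )

    store = AnnotationStore(
        databases={PLEXIN_DATABASE: feats},
        gene_to_transcripts={g: frozenset(ts) for g, ts in gene_tx.items()},
    )
    store.validate()

    ids = [eid for eid, _ in PLEXIN_ZSCORES.values()] + bg_genes
    values = np.concatenate(
        [
            np.array([z for _, z in PLEXIN_ZSCORES.values()]),
            rng.normal(background[0], background[1], size=n_background),
        ]
    )
    measurements = MeasurementTable(identifiers=tuple(ids), values=values)
    return store, measurements
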
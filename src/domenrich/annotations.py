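"""Flat-file annotation stores and identifier-to-domain mapping.

The annotation universe is a collection of partially redundant member
databases (Pfam, SMART, PROSITE, ... as integrated under InterPro umbrella
accessions), loaded from a BioMart-style tab-delimited export: one row per
(gene, transcript, database, feature).  User identifiers are resolved to
Ensembl gene or transcript identifiers through an optional synonym table, then
linked to domain features:

* gene-level identifiers fan out to ALL transcripts of the gene and collect
  the union of their features (alternative splicing means different gene
  products can carry different domains, so a gene-level value is credited to
  every feature any of its transcripts carries);
* transcript/protein-level identifiers link directly to their transcript's
  features.

Redundant (feature, identifier) pairs arising from multiple transcripts are
removed, so each identifier contributes once per feature.  Identifiers that
resolve to zero features are reported as unmapped but stay in the background
population downstream.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ColumnSpec",
    "FeatureRecord",
    "AnnotationStore",
    "IdentifierMap",
    "AssociationMap",
    "load_annotations",
    "load_identifier_map",
    "map_identifiers",
]

ID_LEVELS = ("gene", "transcript")


@dataclass(frozen=True)
class ColumnSpec:
    """Column names of an annotation table (BioMart exports vary)."""

    gene_id: str = "gene_id"
    transcript_id: str = "transcript_id"
    database: str = "database"
    feature_id: str = "feature_id"
    description: str = "description"
    umbrella_id: str = "umbrella_id"
    delimiter: str = "\t"

    def required(self) -> tuple[str, ...]:
        return (
            self.gene_id,
            self.transcript_id,
            self.database,
            self.feature_id,
            self.description,
            self.umbrella_id,
        )


@dataclass(frozen=True)
class FeatureRecord:
    """One domain feature of one member database."""

    feature_id: str
    database_name: str
    description: str
    umbrella_id: str  # InterPro accession, may be empty
    transcript_ids: frozenset[str]


@dataclass
class AnnotationStore:
    """Per-member-database feature records plus the gene/transcript topology.

    ``databases`` maps database name -> feature_id -> :class:`FeatureRecord`;
    feature identifiers are unique within a database but may repeat across
    databases.  Every transcript referenced by a feature belongs to exactly
    one gene in ``gene_to_transcripts``.
    """

    databases: dict[str, dict[str, FeatureRecord]]
    gene_to_transcripts: dict[str, frozenset[str]]
    _transcript_features: dict[str, frozenset[tuple[str, str]]] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def database_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.databases))

    @property
    def transcript_to_gene(self) -> dict[str, str]:
        return {
            t: g for g, ts in self.gene_to_transcripts.items() for t in ts
        }

    def n_features(self, database: str | None = None) -> int:
        if database is not None:
            return len(self.databases.get(database, {}))
        return sum(len(feats) for feats in self.databases.values())

    def transcript_feature_index(self) -> dict[str, frozenset[tuple[str, str]]]:
        """Transcript id -> set of (database, feature_id) it carries."""
        if self._transcript_features is None:
            index: dict[str, set[tuple[str, str]]] = defaultdict(set)
            for db, feats in self.databases.items():
                for fid, rec in feats.items():
                    for t in rec.transcript_ids:
                        index[t].add((db, fid))
            self._transcript_features = {
                t: frozenset(s) for t, s in index.items()
            }
        return self._transcript_features

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`InputError` on breach."""
        known = {t for ts in self.gene_to_transcripts.values() for t in ts}
        counts: dict[str, int] = defaultdict(int)
        for ts in self.gene_to_transcripts.values():
            for t in ts:
                counts[t] += 1
        for db, feats in self.databases.items():
            for fid, rec in feats.items():
                if not rec.transcript_ids:
                    raise InputError(f"feature {db}/{fid} has no transcripts")
                for t in rec.transcript_ids:
                    if t not in known:
                        raise InputError(
                            f"transcript {t} of {db}/{fid} has no parent gene"
                        )
                    if counts[t] != 1:
                        raise InputError(
                            f"transcript {t} belongs to {counts[t]} genes"
                        )

    def to_frame(self, columns: ColumnSpec | None = None) -> pd.DataFrame:
        """Flatten to one row per (gene, transcript, database, feature)."""
        cols = columns or ColumnSpec()
        t2g = self.transcript_to_gene
        rows = []
        for db in sorted(self.databases):
            for fid in sorted(self.databases[db]):
                rec = self.databases[db][fid]
                for t in sorted(rec.transcript_ids):
                    rows.append(
                        (t2g[t], t, db, fid, rec.description, rec.umbrella_id)
                    )
        return pd.DataFrame(rows, columns=list(cols.required()))


@dataclass(frozen=True)
class IdentifierMap:
    """Synonym table translating user identifiers to Ensembl identifiers.

    ``id_level`` is uniform across the table: either every Ensembl identifier
    is a gene id or every one is a transcript id.  One user identifier may map
    to several Ensembl identifiers (ambiguous symbols); mapping fans out to
    all of them.
    """

    entries: frozenset[tuple[str, str]]  # (user_identifier, ensembl_id)
    id_level: str

    def __post_init__(self) -> None:
        if self.id_level not in ID_LEVELS:
            raise InputError(f"id_level must be one of {ID_LEVELS}")
        for uid, eid in self.entries:
            if not uid or not eid:
                raise InputError("identifier map entries must be non-empty strings")

    def lookup(self, *, case_fold: bool = False) -> dict[str, frozenset[str]]:
        table: dict[str, set[str]] = defaultdict(set)
        for uid, eid in self.entries:
            table[uid.casefold() if case_fold else uid].add(eid)
        return {k: frozenset(v) for k, v in table.items()}


@dataclass
class AssociationMap:
    """Deduplicated feature -> user-identifier associations.

    ``unmapped_identifiers`` holds identifiers linked to zero features; they
    are disjoint from every associated identifier set and remain part of the
    background population for testing.
    """

    feature_to_identifiers: dict[tuple[str, str], frozenset[str]]
    unmapped_identifiers: frozenset[str]

    @property
    def mapped_identifiers(self) -> frozenset[str]:
        out: set[str] = set()
        for ids in self.feature_to_identifiers.values():
            out |= ids
        return frozenset(out)


def load_annotations(
    path: str | Path, format_config: ColumnSpec | None = None
) -> AnnotationStore:
    """Load a flat annotation table into an :class:`AnnotationStore`.

    Rows repeating the same (database, feature, transcript) triple collapse to
    one; conflicting descriptions or umbrella accessions for one feature
    resolve to the first occurrence with a logged warning.  A transcript
    listed under two different genes is a hard error.
    """
    cols = format_config or ColumnSpec()
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    try:
        frame = pd.read_csv(
            path, sep=cols.delimiter, dtype=str, keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        raise InputError(f"annotation file is empty: {path}") from None
    missing = [c for c in cols.required() if c not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"annotation file {path} is missing required column(s): "
            + ", ".join(missing)
        )
    if frame.empty:
        raise InputError(f"annotation file has a header but no rows: {path}")

    gene_of: dict[str, str] = {}
    g2t: dict[str, set[str]] = defaultdict(set)
    transcripts: dict[tuple[str, str], set[str]] = defaultdict(set)
    meta: dict[tuple[str, str], tuple[str, str]] = {}
    columns = [frame[c].to_list() for c in cols.required()]
    for gene, transcript, db, fid, desc, umb in zip(*columns):
        gene, transcript, db = gene.strip(), transcript.strip(), db.strip()
        fid, desc, umb = fid.strip(), desc.strip(), umb.strip()
        if not (gene and transcript and db and fid):
            raise InputError(
                "annotation rows need non-empty gene_id, transcript_id, "
                "database and feature_id"
            )
        if gene_of.setdefault(transcript, gene) != gene:
            raise InputError(
                f"transcript {transcript} listed under two genes "
                f"({gene_of[transcript]} and {gene})"
            )
        g2t[gene].add(transcript)
        key = (db, fid)
        transcripts[key].add(transcript)
        if key not in meta:
            meta[key] = (desc, umb)
        elif meta[key] != (desc, umb):
            logger.warning(
                "feature %s/%s has conflicting description/umbrella rows; "
                "keeping the first occurrence",
                db,
                fid,
            )

    databases: dict[str, dict[str, FeatureRecord]] = defaultdict(dict)
    for (db, fid), ts in transcripts.items():
        desc, umb = meta[(db, fid)]
        databases[db][fid] = FeatureRecord(
            feature_id=fid,
            database_name=db,
            description=desc,
            umbrella_id=umb,
            transcript_ids=frozenset(ts),
        )
    store = AnnotationStore(
        databases=dict(databases),
        gene_to_transcripts={g: frozenset(ts) for g, ts in g2t.items()},
    )
    store.validate()
    logger.info(
        "loaded %d features across %d database(s) covering %d gene(s) from %s",
        store.n_features(),
        len(store.databases),
        len(store.gene_to_transcripts),
        path,
    )
    return store


def load_identifier_map(path: str | Path) -> IdentifierMap:
    """Load a synonym table with columns user_id, ensembl_id, level."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"synonym file not found: {path}")
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise InputError(f"synonym file is empty: {path}") from None
    missing = [c for c in ("user_id", "ensembl_id", "level") if c not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"synonym file {path} is missing column(s): " + ", ".join(missing)
        )
    levels = set(frame["level"].str.strip())
    if len(levels) != 1 or not levels <= set(ID_LEVELS):
        raise InputError(
            f"synonym table must use one uniform level from {ID_LEVELS}; got {sorted(levels)}"
        )
    entries = frozenset(
        (u.strip(), e.strip())
        for u, e in zip(frame["user_id"], frame["ensembl_id"])
    )
    return IdentifierMap(entries=entries, id_level=levels.pop())


def map_identifiers(
    measurements,
    idmap: IdentifierMap | None,
    store: AnnotationStore,
    *,
    case_fold: bool = False,
) -> AssociationMap:
    """Resolve every measurement identifier to its domain features.

    Identifiers found in ``idmap`` translate to Ensembl identifiers at the
    map's level; identifiers absent from the map (or when no map is given) are
    tried directly as Ensembl gene then transcript ids.  Gene-level hits fan
    out over all of the gene's transcripts; the resulting (feature,
    identifier) pairs are deduplicated.  An ambiguous synonym fans out to all
    of its Ensembl matches with a logged warning.  Identifiers reaching zero
    features land in ``unmapped_identifiers`` (not an error; they stay in the
    background).
    """
    if not store.databases:
        raise InputError("annotation store is empty")
    t2f = store.transcript_feature_index()
    fold = (lambda s: s.casefold()) if case_fold else (lambda s: s)
    gene_index = {fold(g): g for g in store.gene_to_transcripts}
    transcript_index = {fold(t): t for t in t2f}
    synonym = idmap.lookup(case_fold=case_fold) if idmap is not None else {}

    assoc: dict[tuple[str, str], set[str]] = defaultdict(set)
    unmapped: set[str] = set()
    n_ambiguous = 0
    for uid in measurements.identifiers:
        key = fold(uid)
        targets: list[tuple[str, str]] = []
        if key in synonym:
            matches = synonym[key]
            if len(matches) > 1:
                n_ambiguous += 1
                logger.warning(
                    "identifier %r is ambiguous (%d Ensembl matches); "
                    "fanning out to all of them",
                    uid,
                    len(matches),
                )
            targets = [(eid, idmap.id_level) for eid in sorted(matches)]
        elif key in gene_index:
            targets = [(gene_index[key], "gene")]
        elif key in transcript_index:
            targets = [(transcript_index[key], "transcript")]

        features: set[tuple[str, str]] = set()
        for eid, level in targets:
            if level == "gene":
                for t in store.gene_to_transcripts.get(eid, ()):
                    features |= t2f.get(t, frozenset())
            else:
                features |= t2f.get(eid, frozenset())
        if features:
            for feat in features:
                assoc[feat].add(uid)
        else:
            unmapped.add(uid)

    n_total = len(measurements.identifiers)
    logger.info(
        "mapped %d/%d identifiers to >=1 feature (%d unmapped, %d ambiguous)",
        n_total - len(unmapped),
        n_total,
        len(unmapped),
        n_ambiguous,
    )
    return AssociationMap(
        feature_to_identifiers={k: frozenset(v) for k, v in assoc.items()},
        unmapped_identifiers=frozenset(unmapped),
    )
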
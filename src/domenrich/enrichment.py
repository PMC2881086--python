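"""Enrichment engine: per-feature value sets, tests, and the report.

For every domain feature the associated values form the test set and the
values of ALL other uploaded identifiers (annotated or not) form the
background — the complement within the uploaded population, never an external
genome-wide background.  Each member database is analysed and FDR-corrected
independently, because the databases are partially redundant: pooling them
would penalise every domain for appearing under several accessions.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotations import (
    AnnotationStore,
    AssociationMap,
    FeatureRecord,
    IdentifierMap,
    map_identifiers,
)
from .config import AnalysisConfig
from .errors import InputError
from .rank_stats import bh_adjust, mann_whitney, storey_qvalues

logger = logging.getLogger(__name__)

__all__ = [
    "MeasurementTable",
    "FeatureValueSet",
    "EnrichmentResults",
    "EnrichmentReport",
    "REPORT_COLUMNS",
    "build_value_sets",
    "analyse_database",
    "run_analysis",
    "filter_and_sort",
]

#: Report column order: member database, feature accession, description,
#: number of associated identifiers, median of their values, raw p, BH FDR p,
#: Storey q, rho, InterPro umbrella accession.
REPORT_COLUMNS = (
    "database",
    "feature_id",
    "description",
    "n_identifiers",
    "median",
    "p_value",
    "fdr_p",
    "q_value",
    "rho",
    "umbrella_id",
)


@dataclass(frozen=True)
class MeasurementTable:
    """The complete, unfiltered result list of one experiment.

    One row per user identifier with one finite numeric value (z-score,
    log-fold-change, ...).  Identifiers are unique after ingestion.
    """

    identifiers: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.identifiers) != len(self.values):
            raise InputError("identifiers and values differ in length")
        if len(self.identifiers) == 0:
            raise InputError("measurement table is empty")
        if any(not i for i in self.identifiers):
            raise InputError("empty identifier in measurement table")
        if len(set(self.identifiers)) != len(self.identifiers):
            raise InputError("duplicate identifiers after ingestion")
        if not np.all(np.isfinite(self.values)):
            raise InputError("measurement values must be finite")

    def __len__(self) -> int:
        return len(self.identifiers)

    @property
    def value_of(self) -> dict[str, float]:
        return dict(zip(self.identifiers, self.values.tolist()))

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, float]],
        *,
        duplicate_policy: str = "error",
    ) -> "MeasurementTable":
        ids: list[str] = []
        vals: list[list[float]] = []
        pos: dict[str, int] = {}
        n_dupes = 0
        for uid, val in pairs:
            if uid in pos:
                n_dupes += 1
                if duplicate_policy == "error":
                    raise InputError(
                        f"duplicate identifier {uid!r}; set duplicate_policy to "
                        "'mean', 'median' or 'first' to aggregate"
                    )
                if duplicate_policy != "first":
                    vals[pos[uid]].append(float(val))
            else:
                pos[uid] = len(ids)
                ids.append(str(uid))
                vals.append([float(val)])
        if n_dupes:
            logger.info(
                "collapsed %d duplicate identifier rows by policy %r",
                n_dupes,
                duplicate_policy,
            )
        reduce = np.median if duplicate_policy == "median" else np.mean
        values = np.array([v[0] if len(v) == 1 else float(reduce(v)) for v in vals])
        return cls(identifiers=tuple(ids), values=values)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, *, duplicate_policy: str = "error"
    ) -> "MeasurementTable":
        if frame.shape[1] < 2:
            raise InputError("measurement frame needs two columns: identifier, value")
        it = zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(float))
        return cls.from_pairs(it, duplicate_policy=duplicate_policy)

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        *,
        duplicate_policy: str = "error",
        delimiter: str = "\t",
        has_header: bool | None = None,
    ) -> "MeasurementTable":
        """Read a two-column delimited file; the header row is auto-detected
        (a first line whose second field does not parse as a number is taken
        to be a header) unless ``has_header`` is forced."""
        path = Path(path)
        if not path.exists():
            raise InputError(f"measurement file not found: {path}")
        pairs: list[tuple[str, float]] = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n").rstrip("\r")
                if not line.strip():
                    continue
                fields = line.split(delimiter)
                if len(fields) != 2:
                    raise InputError(
                        f"{path}, line {lineno}: expected 2 columns, got {len(fields)}"
                    )
                uid, raw = fields[0].strip(), fields[1].strip()
                if lineno == 1:
                    if has_header is True:
                        continue
                    if has_header is None and not _parses_as_float(raw):
                        continue
                try:
                    val = float(raw)
                except ValueError:
                    raise InputError(
                        f"{path}, line {lineno}: value {raw!r} is not numeric"
                    ) from None
                if not uid:
                    raise InputError(f"{path}, line {lineno}: empty identifier")
                pairs.append((uid, val))
        if not pairs:
            raise InputError(f"measurement file has no data rows: {path}")
        return cls.from_pairs(pairs, duplicate_policy=duplicate_policy)


def _parses_as_float(token: str) -> bool:
    try:
        value = float(token)
    except ValueError:
        return False
    return np.isfinite(value)


@dataclass(frozen=True)
class FeatureValueSet:
    """One domain feature with its deduplicated identifiers and their values."""

    feature: FeatureRecord
    identifiers: tuple[str, ...]
    values: np.ndarray


def build_value_sets(
    associations: AssociationMap,
    measurements: MeasurementTable,
    min_set_size: int = 2,
    *,
    store: AnnotationStore,
) -> list[FeatureValueSet]:
    """Reverse the mapping: one value set per feature with >= ``min_set_size``
    associated identifiers; smaller features are dropped with a logged count."""
    value_of = measurements.value_of
    out: list[FeatureValueSet] = []
    n_dropped = 0
    for (db, fid), ids in sorted(associations.feature_to_identifiers.items()):
        kept = sorted(i for i in ids if i in value_of)
        if len(kept) < min_set_size:
            n_dropped += 1
            continue
        out.append(
            FeatureValueSet(
                feature=store.databases[db][fid],
                identifiers=tuple(kept),
                values=np.array([value_of[i] for i in kept]),
            )
        )
    if n_dropped:
        logger.info(
            "dropped %d feature(s) below min_set_size=%d", n_dropped, min_set_size
        )
    return out


def analyse_database(
    value_sets: Sequence[FeatureValueSet],
    measurements: MeasurementTable,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Test every feature of ONE member database against the complement of its
    identifier set within the uploaded population, then BH-adjust and compute
    Storey q-values across this database's features only.

    Returns the report rows sorted by raw p-value; the pi0 estimate is stored
    in ``DataFrame.attrs["pi0"]``.
    """
    cfg = config or AnalysisConfig()
    if not value_sets:
        return pd.DataFrame(columns=list(REPORT_COLUMNS))
    dbs = {vs.feature.database_name for vs in value_sets}
    if len(dbs) > 1:
        raise InputError(
            f"analyse_database expects one member database, got {sorted(dbs)}"
        )
    position = {uid: i for i, uid in enumerate(measurements.identifiers)}
    all_values = measurements.values
    rng = np.random.default_rng(cfg.seed)

    rows = []
    for vs in value_sets:
        mask = np.zeros(len(all_values), dtype=bool)
        mask[[position[i] for i in vs.identifiers]] = True
        domain = all_values[mask]
        rest = all_values[~mask]
        res = mann_whitney(
            domain,
            rest,
            exact_threshold=cfg.exact_threshold,
            method=cfg.test_method,
            n_permutations=cfg.n_permutations,
            rng=rng,
        )
        rows.append(
            {
                "database": vs.feature.database_name,
                "feature_id": vs.feature.feature_id,
                "description": vs.feature.description,
                "n_identifiers": len(vs.identifiers),
                "median": float(np.median(domain)),
                "p_value": res.p_value,
                "rho": res.rho,
                "umbrella_id": vs.feature.umbrella_id,
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame) < 2:
        logger.info(
            "database %s has %d testable feature(s); multiple-testing "
            "correction is the identity",
            dbs.pop(),
            len(frame),
        )
    frame["fdr_p"] = bh_adjust(frame["p_value"].to_numpy())
    q, pi0 = storey_qvalues(
        frame["p_value"].to_numpy(),
        cfg.lambda_grid,
        pi0_min_tests=cfg.pi0_min_tests,
    )
    frame["q_value"] = q
    frame = frame.sort_values(
        ["p_value", "feature_id"], kind="mergesort", ignore_index=True
    )[list(REPORT_COLUMNS)]
    frame.attrs["pi0"] = pi0
    return frame


class EnrichmentResults:
    """Result of a fitted enrichment analysis.

    Carries the per-database report table (columns :data:`REPORT_COLUMNS`),
    run metadata (input counts, per-database pi0 estimates, configuration
    snapshot, timestamp) and helpers for triage, export and display.
    """

    def __init__(self, table: pd.DataFrame, metadata: dict, config: AnalysisConfig):
        self.table = table.reset_index(drop=True)
        self.metadata = metadata
        self.config = config

    def __len__(self) -> int:
        return len(self.table)

    # -- triage ------------------------------------------------------------
    def filter_and_sort(
        self,
        *,
        max_fdr_p: float | None = None,
        max_q: float | None = None,
        search: str | None = None,
        sort_by: str | None = None,
        ascending: bool | None = None,
    ) -> "EnrichmentResults":
        """Threshold, search and re-order the report.

        ``sort_by="separation"`` orders rows by |rho - 0.5| descending — the
        recommended triage for rows that already passed a significance
        threshold, since it ranks by how strongly the domain values separate
        from the background.  Any report column name is also accepted.
        ``search`` keeps rows whose description or feature_id contains the
        substring (case-insensitive).
        """
        frame = self.table
        if max_fdr_p is not None:
            frame = frame[frame["fdr_p"] <= max_fdr_p]
        if max_q is not None:
            frame = frame[frame["q_value"] <= max_q]
        if search is not None:
            needle = search.casefold()
            hit = frame["description"].str.casefold().str.contains(
                needle, regex=False
            ) | frame["feature_id"].str.casefold().str.contains(needle, regex=False)
            frame = frame[hit]
        if sort_by is not None:
            if sort_by == "separation":
                key = (frame["rho"] - 0.5).abs()
                order = key.sort_values(
                    ascending=bool(ascending) if ascending is not None else False,
                    kind="mergesort",
                ).index
                frame = frame.loc[order]
            elif sort_by in REPORT_COLUMNS:
                frame = frame.sort_values(
                    sort_by,
                    ascending=True if ascending is None else bool(ascending),
                    kind="mergesort",
                )
            else:
                raise InputError(
                    f"unknown sort column {sort_by!r}; use one of "
                    f"{REPORT_COLUMNS} or 'separation'"
                )
        return EnrichmentResults(frame, self.metadata, self.config)

    def significant(self, alpha: float | None = None) -> "EnrichmentResults":
        """Rows passing BH FDR at ``alpha`` (default: the run's alpha),
        ordered by distribution separation."""
        level = self.config.alpha if alpha is None else alpha
        return self.filter_and_sort(max_fdr_p=level, sort_by="separation")

    # -- export ------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the report table (no metadata) as a TSV with the standard
        column order."""
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        """Write rows plus the metadata block as JSON."""
        payload = {
            "metadata": self.metadata,
            "rows": self.table.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    # -- display -----------------------------------------------------------
    def summary(self, top: int = 10) -> str:
        """Human-readable run summary: mapping counts, per-database family
        sizes and pi0, and the strongest rows."""
        md = self.metadata
        lines = [
            "Domain-family enrichment results",
            "=" * 48,
            f"measurements: {md['n_measurements']}",
            f"identifiers mapped to >=1 feature: {md['n_mapped']}",
            f"unmapped (background only): {md['n_unmapped']}",
            "",
            "database          features   pi0",
        ]
        for db in sorted(md["n_features_tested"]):
            lines.append(
                f"{db:<16}  {md['n_features_tested'][db]:>8}   "
                f"{md['pi0'][db]:.3f}"
            )
        shown = self.table.nsmallest(top, "p_value") if len(self.table) else self.table
        lines += ["", f"top {min(top, len(self.table))} rows by p-value:"]
        with pd.option_context("display.width", 200, "display.max_columns", None):
            lines.append(shown.to_string(index=False))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<EnrichmentResults: {len(self.table)} rows across "
            f"{self.table['database'].nunique() if len(self.table) else 0} database(s)>"
        )


#: The report type; kept under the name the rest of the field would expect.
EnrichmentReport = EnrichmentResults


def run_analysis(
    measurements: MeasurementTable,
    idmap: IdentifierMap | None,
    store: AnnotationStore,
    config: AnalysisConfig | None = None,
) -> EnrichmentResults:
    """End-to-end analysis: map identifiers, build value sets, analyse each
    selected member database independently, and assemble the report.

    Deterministic given inputs, configuration and seed.  Raises
    :class:`InputError` when no identifier maps to any feature.
    """
    cfg = config or AnalysisConfig()
    assoc = map_identifiers(measurements, idmap, store, case_fold=cfg.case_fold)
    if not assoc.feature_to_identifiers:
        sample = sorted(assoc.unmapped_identifiers)[:10]
        raise InputError(
            "no measurement identifier maps to any domain feature; "
            f"sample of unmapped identifiers: {sample}"
        )
    selected = cfg.databases or store.database_names
    unknown = [db for db in selected if db not in store.databases]
    if unknown:
        raise InputError(
            f"unknown database(s) {unknown}; available: {list(store.database_names)}"
        )

    value_sets = build_value_sets(
        assoc, measurements, cfg.min_set_size, store=store
    )
    by_db: dict[str, list[FeatureValueSet]] = {}
    for vs in value_sets:
        by_db.setdefault(vs.feature.database_name, []).append(vs)

    tables = []
    pi0: dict[str, float] = {}
    n_tested: dict[str, int] = {}
    for db in sorted(selected):
        db_sets = by_db.get(db, [])
        frame = analyse_database(db_sets, measurements, cfg)
        pi0[db] = float(frame.attrs.get("pi0", 1.0))
        n_tested[db] = len(frame)
        logger.info("database %s: tested %d feature(s)", db, len(frame))
        if len(frame):
            tables.append(frame)
    table = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=list(REPORT_COLUMNS))
    )
    metadata = {
        "n_measurements": len(measurements),
        "n_mapped": len(measurements) - len(assoc.unmapped_identifiers),
        "n_unmapped": len(assoc.unmapped_identifiers),
        "n_features_tested": n_tested,
        "pi0": pi0,
        "config": cfg.snapshot(),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return EnrichmentResults(table, metadata, cfg)


def filter_and_sort(report: EnrichmentResults, criteria: dict) -> EnrichmentResults:
    """Functional form of :meth:`EnrichmentResults.filter_and_sort`;
    ``criteria`` maps keyword names to values, empty criteria is the identity."""
    return report.filter_and_sort(**criteria)
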
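"""The model-style front end: build once from data, ``fit()`` to get results.

`DomainEnrichment` bundles a measurement table, an annotation store and an
optional synonym map; fitting runs the identifier mapping, the per-feature
Mann-Whitney tests against the complement background, and the per-database
FDR correction, and returns an :class:`~domenrich.enrichment.EnrichmentResults`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from .annotations import (
    AnnotationStore,
    ColumnSpec,
    IdentifierMap,
    load_annotations,
    load_identifier_map,
)
from .config import AnalysisConfig
from .enrichment import EnrichmentResults, MeasurementTable, run_analysis

__all__ = ["DomainEnrichment"]


class DomainEnrichment:
    """Domain-family gene set enrichment model.

    Parameters
    ----------
    measurements
        The complete, unfiltered result list of the experiment.
    store
        Annotation universe (member databases of domain features).
    idmap
        Optional synonym table; omit when the measurement identifiers are
        already Ensembl gene/transcript ids.
    config
        An :class:`AnalysisConfig`; keyword overrides are applied on top.

    Examples
    --------
    >>> from domenrich import DomainEnrichment
    >>> from domenrich.simulate import plexin_fixture
    >>> store, measurements = plexin_fixture(seed=0)
    >>> results = DomainEnrichment(measurements, store).fit()
    >>> results.table.columns[0]
    'database'
    """

    def __init__(
        self,
        measurements: MeasurementTable,
        store: AnnotationStore,
        idmap: IdentifierMap | None = None,
        config: AnalysisConfig | None = None,
        **overrides,
    ):
        base = config or AnalysisConfig()
        self.config = (
            dataclasses.replace(base, **overrides) if overrides else base
        )
        self.measurements = measurements
        self.store = store
        self.idmap = idmap

    @classmethod
    def from_files(
        cls,
        measurements_path: str | Path,
        annotations_path: str | Path,
        synonyms_path: str | Path | None = None,
        *,
        columns: ColumnSpec | None = None,
        config: AnalysisConfig | None = None,
        **overrides,
    ) -> "DomainEnrichment":
        """Build the model from the three flat-file inputs."""
        cfg = config or AnalysisConfig()
        if overrides:
            cfg = dataclasses.replace(cfg, **overrides)
        measurements = MeasurementTable.from_file(
            measurements_path, duplicate_policy=cfg.duplicate_policy
        )
        store = load_annotations(annotations_path, columns)
        idmap = (
            load_identifier_map(synonyms_path) if synonyms_path is not None else None
        )
        return cls(measurements, store, idmap, config=cfg)

    def fit(self) -> EnrichmentResults:
        """Run the full analysis and return the results object."""
        return run_analysis(self.measurements, self.idmap, self.store, self.config)
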
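import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from domenrich import (  # noqa: E402
    AnnotationStore,
    FeatureRecord,
    IdentifierMap,
    MeasurementTable,
)

FIGURE1_ROWS = [
    # gene G1 has transcripts T1 (domains D1, D2) and T2 (domain D1)
    ("G1", "T1", "PFAM", "D1", "domain one", "IPR000001"),
    ("G1", "T1", "PFAM", "D2", "domain two", "IPR000002"),
    ("G1", "T2", "PFAM", "D1", "domain one", "IPR000001"),
    # gene G2 has one transcript with no shared domains
    ("G2", "T3", "PFAM", "D3", "domain three", "IPR000003"),
]

ANNOT_HEADER = "gene_id\ttranscript_id\tdatabase\tfeature_id\tdescription\tumbrella_id"


def write_annotations(path, rows, header=ANNOT_HEADER):
    lines = [header] + ["\t".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def annotation_file(tmp_path):
    return write_annotations(tmp_path / "annotations.tsv", FIGURE1_ROWS)


@pytest.fixture
def fanout_store():
    """In-memory store with the gene→transcripts→domains fan-out topology."""

    def rec(fid, desc, umbrella, transcripts):
        return FeatureRecord(
            feature_id=fid,
            database_name="PFAM",
            description=desc,
            umbrella_id=umbrella,
            transcript_ids=frozenset(transcripts),
        )

    return AnnotationStore(
        databases={
            "PFAM": {
                "D1": rec("D1", "domain one", "IPR000001", ["T1", "T2"]),
                "D2": rec("D2", "domain two", "IPR000002", ["T1"]),
                "D3": rec("D3", "domain three", "IPR000003", ["T3"]),
            }
        },
        gene_to_transcripts={
            "G1": frozenset({"T1", "T2"}),
            "G2": frozenset({"T3"}),
        },
    )


@pytest.fixture
def gene_idmap():
    return IdentifierMap(
        entries=frozenset({("geneA", "G1"), ("geneB", "G2"), ("geneC", "G3")}),
        id_level="gene",
    )


def measurement_table(pairs):
    return MeasurementTable.from_pairs(pairs)


def random_store(rng, n_genes=8, n_features=5, database="PFAM"):
    """Small random store for brute-force property checks."""
    genes = [f"G{i}" for i in range(n_genes)]
    g2t = {
        g: frozenset(f"{g}T{k}" for k in range(rng.integers(1, 4)))
        for g in genes
    }
    feats = {}
    for f in range(n_features):
        transcripts = set()
        for g in rng.choice(genes, size=rng.integers(1, n_genes + 1), replace=False):
            ts = sorted(g2t[g])
            take = rng.integers(1, len(ts) + 1)
            transcripts.update(
                ts[i] for i in rng.choice(len(ts), size=take, replace=False)
            )
        fid = f"D{f}"
        feats[fid] = FeatureRecord(
            feature_id=fid,
            database_name=database,
            description=f"domain {f}",
            umbrella_id="",
            transcript_ids=frozenset(transcripts),
        )
    return AnnotationStore(databases={database: feats}, gene_to_transcripts=g2t)
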
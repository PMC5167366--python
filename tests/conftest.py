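"""Shared fixtures: the synthetic bundle, the built graph, and random
graph generators used by property and round-trip tests."""

from __future__ import annotations

import random

import pytest

from gsknet.fixtures import make_crop_fixture
from gsknet.graph import GenomicLocation, KnowledgeGraph
from gsknet.metamodel import MetaModel
from gsknet.workflow import load_workflow, run_workflow

CLASSES = ["Gene", "Protein", "SNP", "QTL", "Trait", "Publication"]
NAMESPACES = ["ENSEMBL", "UNIPROT", "GRAMENE", "PMID"]
RELATION_TYPES = ["encodes", "control", "is_a", "published_in",
                  "ortholog", "interacts_with"]


@pytest.fixture(scope="session")
def default_meta():
    return MetaModel.default()


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """The synthetic input bundle (seed 7) plus its manifest."""
    out = tmp_path_factory.mktemp("bundle")
    manifest = make_crop_fixture(7, out_dir=out)
    return out, manifest


@pytest.fixture(scope="session")
def built(bundle):
    """The fully integrated graph built by the bundle's workflow."""
    out, manifest = bundle
    spec = load_workflow(str(out / "workflow.yaml"))
    graph, log = run_workflow(spec)
    return graph, log, manifest


def random_graph(rng: random.Random, n_min: int = 3, n_max: int = 40,
                 rel_factor: float = 1.5) -> KnowledgeGraph:
    """A random typed graph with varied accessions, names and attribute
    kinds (integer, decimal, text, location); concepts are created
    without upsert merging so sizes are exact."""
    g = KnowledgeGraph(MetaModel.default())
    n = rng.randint(n_min, n_max)
    ids = []
    for _ in range(n):
        cls = rng.choice(CLASSES)
        accs = [
            (rng.choice(NAMESPACES), f"ACC{rng.randint(1, 3 * n)}",
             rng.random() < 0.1)
            for _ in range(rng.randint(0, 2))
        ]
        names = []
        if rng.random() < 0.6:
            names.append((f"name{rng.randint(1, 40)}", rng.random() < 0.5))
        attrs = {}
        if rng.random() < 0.5:
            attrs["BEGIN"] = rng.randint(1, 10_000)
        if rng.random() < 0.3:
            attrs["Score"] = rng.choice(
                [rng.randint(0, 99), round(rng.uniform(0, 99), 3)])
        if rng.random() < 0.3:
            b = rng.randint(1, 5000)
            attrs["Location"] = GenomicLocation(
                f"chr{rng.randint(1, 3)}", b, b + rng.randint(0, 400),
                rng.choice(["bp", "cM"]), rng.choice([None, "4565"]))
        if rng.random() < 0.4:
            attrs["Description"] = f"desc {rng.randint(1, 9)}"
        cid = g.upsert_concept(
            cls, accessions=accs, names=names, attributes=attrs,
            source=rng.choice(["ENSEMBL", "UNIPROT", "INTEGRATOR"]),
            merge=False)
        ids.append(cid)
    for _ in range(int(rel_factor * n)):
        g.add_relation(rng.choice(ids), rng.choice(ids),
                       rng.choice(RELATION_TYPES), data_source="INTEGRATOR")
    return g


def random_equal_graph(rng: random.Random, n_min: int = 6,
                       n_max: int = 60) -> tuple[KnowledgeGraph, list]:
    """A random graph plus ``equal`` relations between same-class pairs;
    returns (graph, list of equal (a, b) pairs) for oracle comparison."""
    g = random_graph(rng, n_min, n_max, rel_factor=1.0)
    by_class: dict[str, list[int]] = {}
    for c in g.concepts.values():
        by_class.setdefault(c.concept_class, []).append(c.id)
    pairs = []
    for members in by_class.values():
        if len(members) < 2:
            continue
        for _ in range(rng.randint(0, len(members))):
            a, b = rng.sample(members, 2)
            g.add_relation(a, b, "equal", data_source="INTEGRATOR",
                           evidence=("ACC",))
            pairs.append((a, b))
    return g, pairs
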
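"""Shared fixtures: tiny hand-built ontologies, proteomes and studies."""

import textwrap

import pytest

from idpcmp.go_ontology import AnnotationSet, GoDag, GoTerm
from idpcmp.synthetic_data import SyntheticStudyConfig, generate_study


@pytest.fixture
def toy_fasta(tmp_path):
    """Three-entry FASTA with a fragment and a lowercase sequence."""
    path = tmp_path / "toy.fasta"
    path.write_text(
        textwrap.dedent(
            """\
            >P1 first protein GN=GENE1
            MKVLAENS
            >P2 second protein (Fragment)
            mkvaag
            >P3 third
            MKWWTE
            """
        )
    )
    return path


@pytest.fixture
def chain_dag():
    """c is_a b is_a a."""
    return GoDag(
        {
            "GO:a": GoTerm("GO:a", "a", "biological_process"),
            "GO:b": GoTerm("GO:b", "b", "biological_process",
                           parents={"is_a": ("GO:a",)}),
            "GO:c": GoTerm("GO:c", "c", "biological_process",
                           parents={"is_a": ("GO:b",)}),
        }
    )


@pytest.fixture
def diamond_dag():
    """d is_a b, d is_a c; b, c is_a a."""
    return GoDag(
        {
            "GO:a": GoTerm("GO:a", "a", "biological_process"),
            "GO:b": GoTerm("GO:b", "b", "biological_process",
                           parents={"is_a": ("GO:a",)}),
            "GO:c": GoTerm("GO:c", "c", "biological_process",
                           parents={"is_a": ("GO:a",)}),
            "GO:d": GoTerm("GO:d", "d", "biological_process",
                           parents={"is_a": ("GO:b", "GO:c")}),
        }
    )


def make_annotations(label, mapping, expanded=False):
    return AnnotationSet(
        label, {p: frozenset(ts) for p, ts in mapping.items()}, expanded=expanded
    )


@pytest.fixture(scope="session")
def small_study():
    """One small planted study reused by read-only tests."""
    cfg = SyntheticStudyConfig(
        seed=11, n_proteins=200, n_terms=30, n_planted_terms=2,
        planted_class_size=80, term_size_range=(15, 30),
    )
    return generate_study(cfg)
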
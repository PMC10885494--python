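import random

import pytest

from prfscan.synthetic import FixtureSpec, make_corpus


def format_genbank(locus: str, sequence: str, feature_lines: list[str]) -> str:
    """Hand-rolled GenBank flat file (independent of the package's writer)."""
    head = (
        f"LOCUS       {locus}{' ' * max(1, 18 - len(locus))}"
        f"{len(sequence)} bp    DNA     linear   PHG 01-JAN-2000\n"
        f"DEFINITION  synthetic test record.\n"
        "FEATURES             Location/Qualifiers\n"
    )
    body = "".join(feature_lines)
    origin = ["ORIGIN"]
    for i in range(0, len(sequence), 60):
        chunk = sequence[i : i + 60].lower()
        grouped = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        origin.append(f"{i + 1:>9} {grouped}")
    return head + body + "\n".join(origin) + "\n//\n"


def cds_line(location: str, product: str) -> str:
    return (
        f"     CDS             {location}\n"
        f'                     /product="{product}"\n'
    )


@pytest.fixture(scope="session")
def toy_genbank_text() -> str:
    """A two-gene toy record: a plain gene and a join-annotated chaperone."""
    rng = random.Random(2000)
    seq = "".join(rng.choice("ACGT") for _ in range(450))
    return format_genbank(
        "PHAGETOY",
        seq,
        [
            cds_line("1..100", "geneA"),
            cds_line("join(200..300,301..400)", "chaperone"),
        ],
    )


@pytest.fixture(scope="session")
def corpus30():
    """The default study corpus: 30 genomes, 5 families, 1 planted PRF each."""
    return make_corpus(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def corpus_small():
    """A light corpus for pipeline plumbing tests."""
    return make_corpus(
        FixtureSpec(n_genomes=8, n_families=2, genes_per_genome=5, seed=7)
    )
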
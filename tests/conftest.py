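import pytest

from dubscreen import library_model as lib


def enumerated_spacers(n, length=20):
    """Unique spacers by base-4 coding of an integer.

    Fast but NOT Hamming-separated: suitable for simulation/scoring tests
    only, never for the 1-mismatch matcher.
    """
    out = []
    for i in range(n):
        chars = []
        x = i
        for _ in range(length):
            chars.append("ACGT"[x % 4])
            x //= 4
        out.append("".join(chars))
    return out


def toy_catalog(n_genes, guides_per_gene=3, length=20):
    sp = enumerated_spacers(n_genes * guides_per_gene, length)
    return {
        f"G{i:05d}": sp[guides_per_gene * i : guides_per_gene * (i + 1)]
        for i in range(n_genes)
    }


@pytest.fixture(scope="session")
def default_manifest():
    return lib.build_default_library()


@pytest.fixture(scope="session")
def calibration_manifest():
    """200 neutral genes with a deep (1500-guide) non-targeting pool.

    The pool must dwarf the number of scored genes: every gene p-value is
    computed against the same finite null, so the null's ECDF error is what
    a uniformity test across genes actually sees.
    """
    catalog = toy_catalog(200)
    return lib.build_library(catalog, n_nontargeting=1500, seed=12)


@pytest.fixture(scope="session")
def sim_manifest():
    """Medium manifest (200 genes x3 + 60 NT) for recovery simulations."""
    return lib.build_library(toy_catalog(200), n_nontargeting=60, seed=3)
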
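import numpy as np
import pandas as pd
import pytest

from switchtome import SimConfig, simulate
from switchtome.model import CountTable, CoverageTrack, LibraryInfo
from switchtome.programs import ExpressionMatrix

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_bundle():
    """Full simulation at the default study conditions (fixed seed)."""
    return simulate(SimConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_expr(default_bundle):
    from switchtome.programs import normalize_expression
    return normalize_expression(default_bundle["long_counts"],
                                default_bundle["genes"])


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale configuration for pipeline/CLI round trips."""
    return SimConfig(seed=3, genome_length=200_000, n_genes=180,
                     gene_length_mean=800, n_border_transposons=10,
                     long_depth=2e5, fragment_depth=1e5, n_ncrna=6, n_rrna=2)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate(small_config)


def make_track(plus, minus=None, timepoint=0.0, library_id="toy",
               library_size=0.0, bin_size=1):
    plus = np.asarray(plus, dtype=float)
    stranded = minus is not None
    minus = np.asarray(minus, dtype=float) if stranded else None
    return CoverageTrack(library_id, timepoint, stranded, plus, minus=minus,
                         bin_size=bin_size, library_size=library_size)


def toy_expression(values, timepoints, gene_ids=None, lengths=1000,
                   library_size=1e6, kind="long"):
    """ExpressionMatrix with given normalized values (genes x timepoints)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(values.shape[0])]
    libs = [LibraryInfo(f"{kind}_t{t:g}", float(t), kind, library_size)
            for t in timepoints]
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                      columns=[lib.library_id for lib in libs])
    lens = pd.Series(lengths, index=df.index, dtype=float) \
        if np.isscalar(lengths) else pd.Series(lengths, index=df.index)
    return ExpressionMatrix(df, df.copy(), libs,
                            pd.Series(1.0, index=df.columns), lens)


def toy_counts(counts, timepoints, gene_ids=None, kind="long",
               library_sizes=None):
    counts = np.atleast_2d(np.asarray(counts, dtype=int))
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(counts.shape[0])]
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    libs = [LibraryInfo(f"{kind}_t{t:g}", float(t), kind, float(s))
            for t, s in zip(timepoints, library_sizes)]
    df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                      columns=[lib.library_id for lib in libs])
    return CountTable(df, libs)
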
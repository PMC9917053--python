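import pytest

from difcir import (
    ProcessingParams,
    annotate_circles,
    compute_ppgc,
    equalize,
    process_sample,
    scale_by_gene_length,
    worked_toy_dataset,
)


@pytest.fixture(scope="session")
def toy():
    return worked_toy_dataset()


@pytest.fixture(scope="session")
def toy_processed(toy):
    """Toy calls after the full filter -> merge -> JT_min cascade."""
    params = ProcessingParams()
    out = {}
    mito = {}
    for sid, calls in toy.calls_by_sample.items():
        out[sid], m = process_sample(calls, params)
        mito[sid] = [c for c in calls if c.chrom in params.mito_names]
    return out, mito


@pytest.fixture(scope="session")
def toy_tables(toy, toy_processed):
    """Raw / scaled / equalized PpGC tables of the toy dataset."""
    processed, _ = toy_processed
    pairs = [p for sid in processed for p in annotate_circles(processed[sid], toy.genes)]
    raw = compute_ppgc(pairs, toy.sample_sheet, toy.genes)
    scaled = scale_by_gene_length(raw)
    return raw, scaled, equalize(scaled)
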
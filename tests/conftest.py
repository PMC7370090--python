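import pytest

from sigcall import DERecord, DETable, ModelMetadata, load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture
def meta_factory():
    def make(model_id="m1", tissue="eye", **kw):
        defaults = dict(
            model_id=model_id,
            genotype="RasV12 + scrib-",
            tissue=tissue,
            tumor_class="neoplastic",
        )
        defaults.update(kw)
        return ModelMetadata(**defaults)

    return make


@pytest.fixture
def table_factory(meta_factory):
    """Build a DETable from (symbol, log2fc, pvalue) triples.

    log2fc=None marks a not_expressed record.
    """

    def make(rows, **meta_kw):
        meta = meta_factory(**meta_kw)
        records = {}
        for symbol, log2fc, pvalue in rows:
            if log2fc is None:
                records[symbol] = DERecord(symbol=symbol, status="not_expressed")
            else:
                records[symbol] = DERecord(symbol=symbol, log2fc=log2fc, pvalue=pvalue)
        return DETable(meta=meta, records=records)

    return make
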
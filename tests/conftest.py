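import json

import numpy as np
import pandas as pd
import pytest

from paikit import io_formats, pai_pipeline, simgen
from paikit.smr_heidi import GenotypeLdSource


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """The small self-consistent fixture bundle, generated once per session."""
    out = tmp_path_factory.mktemp("bundle")
    paths = simgen.make_fixture_bundle(out, seed=1)
    return paths


@pytest.fixture(scope="session")
def bundle_inputs(bundle):
    mqtl = io_formats.read_mqtl_summary(bundle["mqtl"])
    probes = io_formats.read_probe_table(bundle["probes"])
    promoters = io_formats.read_intervals(bundle["promoters"], kind="bed")
    ld = GenotypeLdSource(io_formats.read_genotype_matrix(bundle["genotypes"]))
    truth = json.loads(open(bundle["truth"]).read())
    return dict(mqtl=mqtl, probes=probes, promoters=promoters, ld=ld,
                truth=truth)


@pytest.fixture(scope="session")
def scan_records(bundle_inputs):
    """Classified records of the full scan on the fixture bundle."""
    recs = pai_pipeline.run_pai_scan(
        bundle_inputs["mqtl"], bundle_inputs["probes"],
        bundle_inputs["promoters"], bundle_inputs["ld"])
    return pai_pipeline.classify_significant(recs)


def mqtl_frame(rows):
    """Build an mQTL-dialect DataFrame from compact row dicts."""
    defaults = dict(probe_id="cg1", probe_chr="1", probe_bp=1_000_000,
                    snp_chr="1", a1="A", a2="G", freq=0.3, n=1000)
    recs = []
    for row in rows:
        r = dict(defaults)
        r.update(row)
        recs.append(r)
    return pd.DataFrame(recs, columns=io_formats.MQTL_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
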
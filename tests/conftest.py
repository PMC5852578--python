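import pandas as pd
import pytest

import srnafrac as sf
from srnafrac import annotate as annotate_mod
from srnafrac import preprocess as preprocess_mod


@pytest.fixture(scope="session")
def cfg():
    return sf.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def ref(cfg):
    return sf.build_reference(cfg)


@pytest.fixture(scope="session")
def library(cfg, ref):
    """Full 10-sample multiplexed library with ground truth."""
    return sf.simulate_library(ref, cfg)


@pytest.fixture(scope="session")
def prep(cfg, library):
    reads, _ = library
    return preprocess_mod.run_preprocess(reads, cfg.barcode_map, cfg.adapter)


@pytest.fixture(scope="session")
def assignments(prep, ref):
    records, _ = prep
    return annotate_mod.assign_category(records, ref)


@pytest.fixture(scope="session")
def gt_records(library):
    """Collapsed insert table built straight from ground truth (no trimming)."""
    _, gt = library
    inserts = {
        sid: list(grp["insert"]) for sid, grp in gt.groupby("sample", sort=False)
    }
    return preprocess_mod.collapse(inserts)


@pytest.fixture(scope="session")
def comp_library(cfg, ref):
    """10,000-read two-sample library for composition-recovery checks."""
    from srnafrac.config import with_overrides

    comp_cfg = with_overrides(
        cfg,
        samples=(("0-1h", "UF"), ("7-8h", "mRNP")),
        reads_per_sample=10_000,
    )
    _, gt = sf.simulate_library(ref, comp_cfg)
    inserts = {
        sid: list(grp["insert"]) for sid, grp in gt.groupby("sample", sort=False)
    }
    records = preprocess_mod.collapse(inserts)
    return comp_cfg, records


@pytest.fixture(scope="session")
def gt_insert_category(library):
    """Ground-truth annotation category per unique insert sequence."""
    _, gt = library
    return gt.drop_duplicates("insert").set_index("insert")["category"]
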
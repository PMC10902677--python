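import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from repseq import Repertoire, repertoire_from_records
from repseq.simulate import PanningSimConfig, simulate_panning, write_campaign

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_rep(entries, sample_name="s", region="CDR3"):
    """entries: list of (clone_id, read_count, nt_seq, aa_seq) tuples; read
    fractions are normalized from counts."""
    total = sum(e[1] for e in entries) or 1
    return repertoire_from_records(
        sample_name,
        [{"clone_id": cid, "read_count": cnt, "read_fraction": cnt / total,
          "nt_seq": nt, "aa_seq": aa} for cid, cnt, nt, aa in entries],
        region=region)


def rep_from_fractions(fracs, sample_name="s"):
    """Repertoire whose clone fractions are exactly `fracs` (counts scaled)."""
    counts = [int(round(f * 10_000)) for f in fracs]
    entries = [(f"c{i}", c, "GCT" * 8, f"PEP{i:03d}") for i, c in enumerate(counts)]
    rep = make_rep(entries, sample_name)
    df = rep.df.copy()
    df["read_fraction"] = list(fracs)
    return rep.with_frame(df)


@pytest.fixture
def tiny_rep():
    return make_rep([("c1", 10, "TGTGCTCGT" * 2, "CARDYW"),
                     ("c2", 5, "TGTGCTCGTTGG" * 2, "CARWCARW"),
                     ("c3", 1, "TGTGATCGT" * 2, "CDRDYW")])


@pytest.fixture(scope="session")
def small_campaign():
    """Deterministic small panning campaign used across test modules."""
    cfg = PanningSimConfig(n_clones_initial=200, n_rounds=2,
                           reads_per_round=5000, seed=11)
    return simulate_panning(cfg)


@pytest.fixture(scope="session")
def campaign_dir(tmp_path_factory, small_campaign):
    out = tmp_path_factory.mktemp("campaign")
    paths = write_campaign(small_campaign, out)
    return paths
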
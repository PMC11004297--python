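"""Shared fixtures: small synthetic studies reused across test modules."""

from __future__ import annotations

import pytest

from bcrclone.model import Rearrangement, Repertoire, SampleMeta
from bcrclone.simulate import StudyConfig, emulate_study, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One emulated study with the default KO-effect settings (in memory)."""
    return simulate_study(StudyConfig(seed=7))


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """The same kind of study written to disk; returns its directory."""
    out = tmp_path_factory.mktemp("study")
    emulate_study(StudyConfig(seed=7), out)
    return out


def make_repertoire(
    clone_abundances: dict[str, int],
    sample_id: str = "s1",
    genotype: str = "WT",
    subset: str = "B-1a",
    locus: str = "IGH",
    v_call: str = "IGHV1-1*01",
    j_call: str = "IGHJ1*01",
    c_call: str = "IGHM",
) -> Repertoire:
    """Hand-built repertoire: one record per clone with the given abundance."""
    meta = SampleMeta(sample_id, genotype, subset, 1)
    records = [
        Rearrangement(
            sequence_id=f"{sample_id}-{i}",
            locus=locus,
            v_call=v_call,
            d_call="IGHD1-1*01" if locus == "IGH" else "",
            j_call=j_call,
            c_call=c_call,
            junction="TGT" + "GCA" * max(1, (len(aa) - 2)) + "TGG",
            junction_aa=aa,
            productive=True,
            abundance=abundance,
            sample_id=sample_id,
        )
        for i, (aa, abundance) in enumerate(sorted(clone_abundances.items()))
    ]
    return Repertoire(meta, records)
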
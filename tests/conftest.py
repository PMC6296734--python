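"""Shared fixtures: a small planted dataset and a deterministic promoter builder."""

from __future__ import annotations

import numpy as np
import pytest

from regulonminer.config import PipelineConfig
from regulonminer.synthetic_data import GeneratorConfig, build_dataset

#: Background for hand-built promoter fragments: an AC-repeat cannot contain
#: any subsite, sigma-54 anchor pair or IHF consensus, so every motif hit in
#: a constructed fragment is a planted one.
def _ac_background(n: int) -> list[str]:
    return list(("AC" * (n // 2 + 1))[:n])


def build_promoter(
    subsites: list[tuple[str, int]] | None = None,
    sigma_center: int | None = -127,
    ihf_start: int | None = -189,
    length: int = 520,
) -> tuple[str, int]:
    """A promoter fragment in coding orientation, ATG at the final 3 bases.

    ``subsites`` are (6-mer, ATG-relative start) pairs; ``sigma_center`` is
    the reported (half-away-rounded) centre of a planted GG-N10-GC element;
    ``ihf_start`` the ATG-relative start of a planted IHF consensus instance.
    """
    atg = length - 3
    seq = _ac_background(length)
    seq[atg:] = list("ATG")

    def put(rel_start: int, element: str) -> None:
        idx = atg + rel_start
        assert 0 <= idx and idx + len(element) <= atg, "element outside fragment"
        seq[idx : idx + len(element)] = list(element)

    if sigma_center is not None:
        put(sigma_center - 6, "GG" + "A" * 10 + "GC")
    if ihf_start is not None:
        put(ihf_start, "AATCAACGCGTTA")  # matches WATCAANNNNTTR exactly
    for motif, rel_start in subsites or []:
        put(rel_start, motif)
    return "".join(seq), atg


@pytest.fixture(scope="session")
def promoter_builder():
    return build_promoter


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_generator_config() -> GeneratorConfig:
    return GeneratorConfig(
        genome_length=30_000,
        n_genes=14,
        n_targets=3,
        n_decoy_orientation=2,
        n_decoy_spacing=2,
        n_decoy_subthreshold=2,
        n_background_peaks=5,
    )


@pytest.fixture(scope="session")
def small_dataset(small_generator_config):
    return build_dataset(small_generator_config, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
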
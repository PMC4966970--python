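import pytest

from gvkit.simulate import PRESETS, generate_study


@pytest.fixture(scope="session")
def easy_study():
    """One shared small synthetic study (genome, truth, proteome, contigs)."""
    return generate_study(PRESETS["easy"], seed=7)


@pytest.fixture(scope="session")
def easy_annotation(easy_study):
    from gvkit.orfs import annotate_genome

    genome, truth, proteome, contigs = easy_study
    ann, dropped = annotate_genome(genome, proteome, seed=7, anchor_product="granulin")
    return ann, dropped
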
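import json
from types import SimpleNamespace

import pytest

from saltlnc.pipeline import prepare_run_dir, run_pipeline
from saltlnc.simulate import SynthConfig, generate_counts, generate_transcriptome

#: analysis dispersion used for synthetic runs (matched order of magnitude to
#: the generator, which draws at 0.05; see docs/methods.md)
SYNTH_DE_CONFIG = {"de": {"dispersion": 0.1}}


@pytest.fixture(scope="session")
def synth():
    """The default 200-transcript synthetic study (seed 1) with its truth."""
    config = SynthConfig(seed=1)
    transcripts, truth, refs, matures = generate_transcriptome(config)
    counts = generate_counts(truth, config, [t.id for t in transcripts])
    return SimpleNamespace(
        config=config,
        transcripts=transcripts,
        truth=truth,
        refs=refs,
        matures=matures,
        counts=counts,
        by_id={t.id: t for t in transcripts},
    )


def make_run(synth, directory):
    prepare_run_dir(directory, synth.transcripts, synth.counts, synth.refs, synth.matures)
    synth.truth.to_json(directory / "truth.json")
    manifest = run_pipeline(directory, SYNTH_DE_CONFIG)
    report = json.loads((directory / "report.json").read_text())
    return SimpleNamespace(dir=directory, manifest=manifest, report=report)


@pytest.fixture(scope="session")
def pipeline_run(synth, tmp_path_factory):
    """One full pipeline execution over the synthetic study."""
    return make_run(synth, tmp_path_factory.mktemp("run"))
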
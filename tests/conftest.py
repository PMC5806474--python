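from __future__ import annotations

import pytest

from varkin.pipeline import PipelineRunner, load_config
from varkin.simulate import MODELS, simulate_model_directory
from varkin.vcf_io import read_vcf


@pytest.fixture(scope="session")
def model_runs(tmp_path_factory):
    """End-to-end pipeline runs for all seven simulated inheritance models.

    Each entry: simulation artifacts (truth, paths), the RunResult, and the
    raw (pre-pipeline) per-individual variant lists for oracle replays.
    """
    runs = {}
    for model in MODELS:
        d = tmp_path_factory.mktemp(f"model_{model}")
        sim = simulate_model_directory(model, seed=1, outdir=d, n_background=500)
        config = load_config(sim["config_path"])
        result = PipelineRunner(config).run()
        raw = {}
        for path in sim["vcf_paths"]:
            iid = path.stem.split("_", 1)[1]
            _, variants = read_vcf(path)
            raw[iid] = variants
        runs[model] = {
            "dir": d,
            "sim": sim,
            "truth": sim["truth"],
            "config": config,
            "result": result,
            "raw": raw,
        }
    return runs


@pytest.fixture(scope="session")
def small_universe(tmp_path_factory):
    """A compact simulated universe (genome, gene map, tables), no family."""
    from varkin.simulate import SimulationSpec, generate_universe

    d = tmp_path_factory.mktemp("universe")
    spec = SimulationSpec(seed=7, n_background_variants=150)
    return generate_universe(spec, d)


def members_for(truth, ped):
    """Oracle-format member dicts from a parsed pedigree."""
    from varkin.vcf_io import Affection, Sex

    out = []
    for ind in ped.members(truth.family_id):
        out.append(
            {
                "iid": ind.individual_id,
                "sex": "1" if ind.sex is Sex.MALE else "2",
                "affected": ind.affected is Affection.AFFECTED,
                "father": ind.father_id,
                "mother": ind.mother_id,
            }
        )
    return out
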
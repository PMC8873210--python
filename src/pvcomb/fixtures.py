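"""Generate example inputs: the packaged meta-analysis table, simulation
configs, and seeded random p-value vectors with known dependence."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from .correlation import CorrelationSpec
from .meta import FIXTURE_NAME
from .simulate import EffectSpec, sample_mvn, table1_configs, three_sided_pvalues
from .io import write_sim_config

__all__ = ["generate_fixtures"]


def generate_fixtures(output_dir, seed: int = 0) -> list[Path]:
    """Write example files into ``output_dir``; deterministic under seed.

    Emits (a) the 12-study OR/CI table, (b) the null-calibration grid
    configs, and (c) three p-value vectors with AR(1)-correlated,
    independent, and rank-deficient dependence for tutorials.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    target = out / FIXTURE_NAME
    target.write_bytes(resources.files("pvcomb.data").joinpath(FIXTURE_NAME).read_bytes())
    written.append(target)

    for cfg in table1_configs(n_replicates=100_000, seed=seed):
        path = out / f"table1_{cfg.spec.model}_k{cfg.spec.k}.yaml"
        write_sim_config(cfg, path)
        written.append(path)

    rng = np.random.default_rng(seed)
    specs = {
        "pvalues_ar1_k10.csv": CorrelationSpec("expo", 10, 0.5),
        "pvalues_indep_k10.csv": CorrelationSpec("expo", 10, 0.0),
        "pvalues_singular_k10.csv": CorrelationSpec("sig", 10, 0.5),
    }
    for name, spec in specs.items():
        z = sample_mvn(spec, EffectSpec(), 1, rng)[0]
        p = three_sided_pvalues(z)["two"]
        path = out / name
        path.write_text("p\n" + "\n".join(f"{v:.17g}" for v in p) + "\n")
        written.append(path)
    return written
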
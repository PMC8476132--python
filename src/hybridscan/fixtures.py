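"""Generation of small on-disk datasets for any named scenario.

A fixture is a phased, AA-polarized VCF plus a truth JSON (locus positions
and windows, parameters, seed), produced by the simulator at a desk scale
chosen so the whole thing runs in minutes.  Identical preset + seed gives
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

from .params import SCENARIOS, scenario_params
from .sim import simulate_scenario
from .spectra import n_windows_for
from .vcfio import write_vcf

__all__ = ["generate_fixture", "DESK_SCALE", "DESK_GENOME_SHRINK", "DESK_WINDOW_SIZE"]

# Desk-scale defaults: sizes and times shrunk 20-fold, the chromosome
# represented by 5 Mb tiled into 1,000 windows of 5 kb.
DESK_SCALE = 20
DESK_GENOME_SHRINK = 100
DESK_WINDOW_SIZE = 5_000


def generate_fixture(
    preset: str,
    seed: int,
    out_dir,
    scale: int = DESK_SCALE,
    genome_shrink: int = DESK_GENOME_SHRINK,
    window_size: int = DESK_WINDOW_SIZE,
    sample_generations: tuple[int, ...] | None = None,
    burn_in: str = "coalescent",
) -> dict[str, list[str]]:
    """Simulate a named scenario at desk scale and write VCF + truth JSON.

    Returns the mapping ``{"vcf": [...], "truth": [...]}`` of written paths
    (one VCF per sampling generation).
    """
    if preset not in SCENARIOS:
        raise KeyError(f"unknown preset {preset!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = scenario_params(preset, seed=seed).scaled(scale, genome_shrink)
    gens = tuple(sample_generations or params.sample_generations)
    samples = simulate_scenario(
        params, burn_in=burn_in, sample_generations=gens, tag=preset
    )

    # Under pure neutrality the loci carry no incompatibility to detect.
    selected = params.eps != 0.0 or params.s_a != 0.0 or params.s_b != 0.0
    locus_windows = (
        [params.pos_A // window_size, params.pos_B // window_size] if selected else []
    )
    truth = {
        "preset": preset,
        "seed": seed,
        "scale": scale,
        "genome_shrink": genome_shrink,
        "window_size": window_size,
        "n_windows": n_windows_for(params.L, window_size),
        "pos_A": params.pos_A,
        "pos_B": params.pos_B,
        "locus_windows": locus_windows,
        "params": {k: v for k, v in asdict(params).items()},
    }

    stem = preset.replace(" ", "_").replace(".", "").lower()
    written = {"vcf": [], "truth": []}
    for gen, sample in sorted(samples.items()):
        vcf_path = out_dir / f"{stem}_seed{seed}_gen{gen}.vcf"
        write_vcf(sample, vcf_path, metadata={"preset": preset, "seed": seed})
        written["vcf"].append(str(vcf_path))
    truth_path = out_dir / f"{stem}_seed{seed}_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, default=str))
    written["truth"].append(str(truth_path))
    return written
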
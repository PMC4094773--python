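"""Shared helper: build (or reuse) the synthetic dataset the examples analyse."""

from pathlib import Path

from nbipscan import SimConfig, simulate

OUT = Path(__file__).parent / "example_output"


def dataset(seed: int = 1) -> Path:
    sim = OUT / "sim"
    if not (sim / "genome.fa").exists():
        print(f"generating synthetic dataset (seed {seed}) under {sim} ...")
        simulate(SimConfig(rng_seed=seed), sim)
    return sim
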
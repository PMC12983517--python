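"""Shared paths and the analysis seed for the numbered drivers."""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 20_260_101

RESULTS.mkdir(exist_ok=True)
SCRATCH.mkdir(exist_ok=True)
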
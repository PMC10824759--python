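"""Shared run-directory location and config for the numbered drivers."""

from pathlib import Path

from pausekit.config import RunConfig

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "synthetic_run"
SEED = 1


def config() -> RunConfig:
    return RunConfig(seed=SEED)
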
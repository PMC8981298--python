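from pathlib import Path

from freegait.pipeline import RunConfig

CONFIG = Path(__file__).parent / "config.yaml"


def load_config() -> RunConfig:
    cfg = RunConfig.from_yaml(CONFIG)
    cfg.validate()
    return cfg
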
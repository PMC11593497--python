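import pytest

import ceutil
from ceutil.parameters import AnalysisConfig, StrategyArm


@pytest.fixture(scope="session")
def base_config() -> AnalysisConfig:
    """The packaged base-case fixture configuration."""
    return ceutil.load_config(ceutil.base_case_config_path())


@pytest.fixture()
def int_arm() -> StrategyArm:
    return StrategyArm("INT", mean_cost=317.73, mean_effect=0.23)


@pytest.fixture()
def con_arm() -> StrategyArm:
    return StrategyArm("CON", mean_cost=293.93, mean_effect=0.20)


@pytest.fixture()
def write_config(tmp_path):
    """Write a YAML config dict to a temp file and return its path."""
    import yaml

    def _write(data, name="config.yaml"):
        path = tmp_path / name
        path.write_text(yaml.safe_dump(data))
        return path

    return _write


@pytest.fixture()
def minimal_config_dict():
    return {
        "strategies": [
            {"name": "INT", "mean_cost": 317.73, "mean_effect": 0.23},
            {"name": "CON", "mean_cost": 293.93, "mean_effect": 0.20},
        ],
    }
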
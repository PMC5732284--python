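import pytest

from dimrl.agents import AgentConfig, simulate_session
from dimrl.task import SessionArrays, TaskConfig, main_task


@pytest.fixture
def main_config() -> TaskConfig:
    return main_task(seed=0)


@pytest.fixture
def short_config() -> TaskConfig:
    """A 64-trial session, enough structure for fast end-to-end tests."""
    return TaskConfig(n_stages=2, seed=0)


def make_session(kind="fixed_policy", policy_id=7, seed=0, config=None, **kw):
    """One synthetic session as (records, score, agent, arrays)."""
    config = config or main_task()
    agent_config = AgentConfig(kind=kind, policy_id=policy_id, seed=seed, **kw)
    records, score, agent = simulate_session(agent_config, config)
    return records, score, agent, SessionArrays.from_records(records)


@pytest.fixture
def fixed7_session():
    """A deterministic session from a policy-7 learner on the main task."""
    return make_session(kind="fixed_policy", policy_id=7, seed=11)


@pytest.fixture
def random_session():
    return make_session(kind="random", seed=5)
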
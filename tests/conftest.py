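"""Shared fixtures.

The heavyweight fixture is a single end-to-end experiment run (20 simulated
16-taxon gene sets, all three guide-tree conditions, heads-or-tails
trimming on) shared by the acceptance tests that measure different aspects
of the same study conditions.
"""

import dendropy
import pytest

from gapguide.experiment import ExperimentConfig, run_experiment


def tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


@pytest.fixture(scope="session")
def experiment_run():
    """Desk-scale replica of the three-guide-tree experiment."""
    config = ExperimentConfig(n_sets=20, seed=0, restarts=2, trimming=True)
    return run_experiment(config)
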
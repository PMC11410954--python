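"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

import fedgnn as f


@pytest.fixture(scope="session")
def tiny_spec():
    # small but learnable: strong planted signal on a 20-gene network
    return f.SyntheticSpec(
        n_genes=20,
        attachment_edges=2,
        n_patients_per_class=20,
        signal_size=4,
        effect_size=2.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    ppi, signal, cohort = f.generate_dataset(tiny_spec)
    graphs = f.build_patient_graphs(cohort, ppi)
    return ppi, signal, cohort, graphs


@pytest.fixture(scope="session")
def tiny_config():
    return f.GNNConfig(epochs=15, seed=1)


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset, tiny_config):
    _, _, _, graphs = tiny_dataset
    return f.train_gnn(graphs, tiny_config)


@pytest.fixture(scope="session")
def tiny_local_result(tiny_dataset, tiny_config):
    _, _, _, graphs = tiny_dataset
    cfg = f.ClientRunConfig(gnn=tiny_config, n_members=5, member_size=3, seed=3)
    return f.train_local(graphs, cfg)


def make_fed_inputs(n_clients, n_members, member_size=2, seed=0, epochs=3, n_genes=12):
    """Small per-client datasets and configs for protocol-level tests."""
    spec = f.SyntheticSpec(
        n_genes=n_genes,
        n_patients_per_class=8 * n_clients,
        signal_size=3,
        effect_size=2.5,
        seed=seed,
    )
    ppi, signal, cohort = f.generate_dataset(spec)
    graphs = f.build_patient_graphs(cohort, ppi)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(graphs))
    chunk = len(graphs) // n_clients
    client_graphs = {
        f"client{i}": [graphs[j] for j in order[i * chunk : (i + 1) * chunk]]
        for i in range(n_clients)
    }
    cfgs = {
        cid: f.ClientRunConfig(
            gnn=f.GNNConfig(epochs=epochs, seed=seed + i),
            n_members=n_members,
            member_size=member_size,
            seed=seed + i,
        )
        for i, cid in enumerate(client_graphs)
    }
    return client_graphs, cfgs, cohort, signal
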
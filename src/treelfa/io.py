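"""HDF5 archives for posterior samples and topic sets."""

from __future__ import annotations

import numpy as np

from .generative import TopicState
from .inference import ChainRun, ChainSchedule, PosteriorSamples
from .postprocess import TopicSet


def save_topic_state(path, state: TopicState) -> None:
    """Archive a TopicState as named datasets I, phi, rho."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("I", data=state.I)
        f.create_dataset("phi", data=state.phi)
        f.create_dataset("rho", data=np.array([state.rho01, state.rho11]))


def load_topic_state(path) -> TopicState:
    import h5py

    with h5py.File(path, "r") as f:
        rho = f["rho"][()]
        return TopicState(I=f["I"][()], phi=f["phi"][()],
                          rho01=float(rho[0]), rho11=float(rho[1]))


def save_posterior(path, samples: PosteriorSamples) -> None:
    """Write per-chain groups with datasets phi/I/rho/N plus alpha and the
    schedule as root attributes."""
    import h5py

    sch = samples.schedule
    with h5py.File(path, "w") as f:
        f.attrs["alpha"] = np.asarray(samples.alpha, dtype=float)
        for key in ("n_chains", "burn_in", "n_samples", "thin_interval"):
            f.attrs[key] = getattr(sch, key)
        f.attrs["em_stage1"] = sch.em_stage1
        f.attrs["em_stage2"] = sch.em_stage2
        f.attrs["mode"] = sch.mode
        if samples.seed is not None:
            f.attrs["seed"] = str(samples.seed)
        for i, chain in enumerate(samples.chains):
            g = f.create_group(f"chain{i}")
            for name in ("phi", "I", "rho", "N"):
                g.create_dataset(name, data=getattr(chain, name))
            if chain.seed is not None:
                g.attrs["seed"] = str(chain.seed)


def load_posterior(path) -> PosteriorSamples:
    import h5py

    with h5py.File(path, "r") as f:
        sch = ChainSchedule(
            n_chains=int(f.attrs["n_chains"]),
            burn_in=int(f.attrs["burn_in"]),
            n_samples=int(f.attrs["n_samples"]),
            thin_interval=int(f.attrs["thin_interval"]),
            em_stage1=tuple(int(x) for x in f.attrs["em_stage1"]),
            em_stage2=tuple(int(x) for x in f.attrs["em_stage2"]),
            mode=str(f.attrs["mode"]),
        )
        chains = []
        for i in range(sch.n_chains):
            g = f[f"chain{i}"]
            chains.append(ChainRun(
                phi=g["phi"][()], I=g["I"][()], rho=g["rho"][()],
                N=g["N"][()], seed=g.attrs.get("seed"),
            ))
        return PosteriorSamples(
            chains=chains, alpha=np.asarray(f.attrs["alpha"]),
            schedule=sch, seed=f.attrs.get("seed"),
        )


def save_topic_set(path, ts: TopicSet) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("topics", data=ts.topics)
        f.create_dataset("support", data=ts.support)
        if ts.alpha is not None:
            f.create_dataset("alpha", data=ts.alpha)


def load_topic_set(path) -> TopicSet:
    import h5py

    with h5py.File(path, "r") as f:
        return TopicSet(
            topics=f["topics"][()],
            support=f["support"][()],
            alpha=f["alpha"][()] if "alpha" in f else None,
        )
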
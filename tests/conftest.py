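import pytest

import foreignscan as fs


def small_synth_config(seed: int = 0, **overrides) -> fs.SyntheticConfig:
    """A reduced two-replicon bundle (200 genes) for fast simulations."""
    cfg = fs.SyntheticConfig(
        seed=seed,
        replicons=[
            fs.RepliconSpec("chr", 230_000, 180, "native"),
            fs.RepliconSpec("pMEG1", 32_000, 20, "foreign"),
        ],
        n_internal_tss_tus=2,
        n_orphan_genes=3,
        prophage=None,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def small_run():
    """One generated small bundle shared by read-only tests."""
    cfg = small_synth_config(seed=7)
    bundle, truth = fs.generate_genome(cfg)
    tus, tss = fs.generate_tu_and_tss(bundle, truth, cfg)
    de, tpm = fs.generate_de_table(bundle, truth, cfg)
    return {"cfg": cfg, "bundle": bundle, "truth": truth, "tus": tus,
            "tss": tss, "de": de, "tpm": tpm}
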
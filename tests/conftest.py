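import warnings

import numpy as np
import pandas as pd
import pytest

import mpradesign as m


@pytest.fixture(scope="session")
def small_cfg():
    """Small, fast generator configuration shared across module tests."""
    return m.SynthConfig(
        n_variants=3000,
        positive_fraction=0.05,
        n_site_scores=20,
        n_tissue_annotations=10,
        effect_size=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_variants(small_cfg):
    return m.generate_variants(small_cfg)


def make_variant_frame(afs, tss=None, labels=None, start_pos=1):
    """Hand-built variant table for targeted matching tests."""
    n = len(afs)
    tss = tss if tss is not None else [1.0] * n
    labels = labels if labels is not None else [0] * n
    df = pd.DataFrame(
        {
            "CHROM": "chr1",
            "POS": np.arange(start_pos, start_pos + n),
            "REF": "A",
            "ALT": "C",
            "AF": np.asarray(afs, float),
            "TSS_SCORE": np.asarray(tss, float),
            "LABEL": labels,
            "SOURCE": "expA",
        }
    )
    df.index = pd.Index([f"v{start_pos + i}" for i in range(n)], name="VARIANT_ID")
    return df


@pytest.fixture(scope="session")
def trained_pipeline():
    """A trained classifier on a small matched cohort with planted signal.

    Session-scoped because training is the expensive step; tests treat the
    result as read-only.
    """
    cfg = m.SynthConfig(
        n_variants=12000,
        positive_fraction=0.01,
        n_site_scores=30,
        n_tissue_annotations=10,
        effect_size=2.0,
        seed=3,
    )
    v = m.generate_variants(cfg)
    positives = v[v.LABEL == 1].iloc[:100]
    pool = v[v.LABEL == 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coh = m.match_controls(positives, pool, ratio=10, seed=3)
    coh = m.split_holdout(coh, 0.2, seed=3)
    rec = coh.records
    scores = m.generate_site_scores(v, cfg)
    nbhd_all = m.generate_neighborhood_tracks(v, cfg)
    store = {vid: nbhd_all[i] for i, vid in enumerate(v.index)}
    bundles, _ = m.assemble_features(rec, scores, store)
    site, nbhd = m.stack_bundles(bundles)
    rec = rec.loc[[b.variant_id for b in bundles]]
    y = (rec["ROLE"] == "positive").to_numpy().astype(float)
    tr = (rec["SPLIT"] == "train").to_numpy()
    std = m.Standardizer().fit(site[tr], nbhd[tr])
    xs_tr, xn_tr = std.transform(site[tr], nbhd[tr])
    xs_va, xn_va = std.transform(site[~tr], nbhd[~tr])
    spec = m.ModelSpec(l_site=site.shape[1])
    net = m.build_model(spec, seed=3)
    result = m.train(net, xs_tr, xn_tr, y[tr], m.TrainConfig(epochs=10, seed=3))
    return {
        "cfg": cfg, "cohort": coh, "records": rec, "spec": spec, "net": net,
        "std": std, "result": result, "y": y, "train_mask": tr,
        "xs_tr": xs_tr, "xn_tr": xn_tr, "xs_va": xs_va, "xn_va": xn_va,
        "site": site, "nbhd": nbhd,
    }
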
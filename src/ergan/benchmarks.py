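"""End-to-end benchmark drivers at the desk-scale study conditions.

These functions run the package's public pipeline on the canonical fixture
populations and return raw per-seed results.  They back both the heavier
property tests and the reproduction script, so that every reported number
comes from one code path.
"""

from __future__ import annotations

import numpy as np

from . import cgan as cgan_mod
from . import classify as clf_mod
from . import cwt as cwt_mod
from . import evaluate as ev_mod
from . import fixtures as fx
from . import presets
from .dataio import normalize, split_train_test


def _ba(y_true, labels) -> float:
    rep = ev_mod.compute_metrics(ev_mod.confusion(y_true, labels))
    return rep.balanced_accuracy


def classifier_battery(
    family: str = "TST",
    n_seeds: int = 20,
    n_fit: int = 96,
    n_val: int = 24,
    n_test: int = 320,
    base_seed: int = 0,
) -> dict[str, list[float]]:
    """Held-out balanced accuracy over training seeds, for a strongly
    separable population and for label-shuffled (null) data.

    The datasets are fixed; the seed drives weight initialisation, batch
    order and (for the null arm) the label permutation, giving a seed band
    for the ceiling (separable) and null behaviours.
    """
    if family not in ("TST", "ViT"):
        raise ValueError(f"unknown family {family!r}")
    out: dict[str, list[float]] = {}
    for arm, (pop, shape) in (
        ("separable", presets.separable_population(101)),
        ("null", presets.null_population(202)),
    ):
        ds = normalize(fx.generate_dataset(pop, shape))
        X, y = ds.X, ds.y
        idx = np.random.default_rng(7).permutation(len(ds))
        fit, val, te = (
            idx[:n_fit],
            idx[n_fit : n_fit + n_val],
            idx[n_fit + n_val : n_fit + n_val + n_test],
        )
        if family == "ViT":
            imgs = cwt_mod.scalogram_batch(X[np.concatenate([fit, val, te])])
            Xf = imgs[: len(fit)]
            Xv = imgs[len(fit) : len(fit) + len(val)]
            Xt = imgs[len(fit) + len(val) :]
        else:
            Xf, Xv, Xt = X[fit], X[val], X[te]
        bas = []
        for k in range(n_seeds):
            seed = base_seed + k
            yf, yv = y[fit], y[val]
            if arm == "null":
                r = np.random.default_rng(9000 + seed)
                yf, yv = r.permutation(yf), r.permutation(yv)
            if family == "TST":
                m = clf_mod.train_tst(Xf, yf, Xv, yv, presets.DESK_TST, seed=seed)
            else:
                m = clf_mod.train_vit(Xf, yf, Xv, yv, presets.DESK_VIT, seed=seed)
            pred = clf_mod.predict(m, Xt)
            bas.append(_ba(y[te], pred["label"]))
        out[arm] = bas
    return out


def augmentation_benefit(seeds=range(5), effective_epochs: int = 100):
    """Pooled-strength TST comparison: real-only vs real+synthetic.

    Per seed: generate the moderately separable nine-strength population,
    run the full protocol (75:25 hold-out, CGAN on the train side, 2:1
    augmentation, five-fold CV evaluated on the untouched test side) and
    return the two fold-averaged balanced accuracies.
    """
    results = []
    for seed in seeds:
        ds = fx.generate_dataset(presets.headline_population(seed))
        table = ev_mod.run_experiment(
            ds,
            ev_mod.ExperimentGrid(strengths=("all",), families=("TST",)),
            cgan_cfg=presets.desk_cgan_config(seed, effective_epochs),
            tst_cfg=presets.DESK_TST_FAST,
            seed=seed,
        )
        real = float(table[table.condition == "real_only"].iloc[0]["ba"])
        aug = float(table[table.condition == "real_plus_synthetic"].iloc[0]["ba"])
        results.append((real, aug))
    return results


def conditional_fidelity(
    seeds=range(10),
    effective_epochs: int = 60,
    n_synth: int = 30,
):
    """Class-conditional sampling check on the group-effect-0.7 population.

    Per seed: train the desk CGAN, sample both classes, and report the
    mean b-wave peak (20-45 ms window) per class plus the Pearson
    correlation between per-class mean synthetic and mean real waveforms.
    """
    rows = []
    for seed in seeds:
        ds = fx.generate_dataset(presets.fidelity_population(seed))
        split = split_train_test(ds, 0.25, seed=seed)
        train = normalize(split.train)
        model = cgan_mod.train_cgan(
            train, presets.desk_cgan_config(seed, effective_epochs)
        )
        t = ds.grid.times
        bwin = (t >= 20) & (t <= 45)
        row = {"seed": seed}
        for cls in (0, 1):
            synth = cgan_mod.sample_synthetic(model, cls, n_synth, seed=seed + 5000)
            real_mean = split.train.X[split.train.y == cls].mean(axis=0)
            row[f"peak{cls}"] = float(synth.X[:, bwin].max(axis=1).mean())
            row[f"r{cls}"] = float(
                np.corrcoef(synth.X.mean(axis=0), real_mean)[0, 1]
            )
        row["order_ok"] = row["peak0"] > row["peak1"]
        rows.append(row)
    return rows
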
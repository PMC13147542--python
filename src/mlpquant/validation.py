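"""End-to-end validation studies on ground-truth synthetic fixtures.

Each function generates its inputs with the :mod:`mlpquant.synth`
generators, runs the corresponding analysis pipeline, and returns summary
metrics. These studies back the package's quantitative claims (recovery
accuracy, test calibration, oracle agreement) and are executed both by the
test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from . import imaging, qtlrf, screenstats, synth, varianteffects
from .flocculation import score_plate
from .varianteffects import impute_flanked


def imaging_recovery(
    seeds: range = range(1, 21),
    noise_sd: float = 3.0,
    min_pre_density: float = 0.2,
) -> dict:
    """Recover planted adhesion ratios and layout shifts from rendered plates.

    For each seed a pre/post plate pair is rendered with a planted rigid
    shift, the reference layout (built once from a filled plate) is fitted,
    both images are measured with it, and recovered ratios are compared with
    the planted truth for positions whose expected prewash density reaches
    ``min_pre_density``.
    """
    filled_spec = synth.PlateSpec(
        densities=np.full((8, 12), 0.8),
        ratios=np.ones((8, 12)),
        noise_sd=1.0,
        seed=0,
    )
    filled, _, _ = synth.render_plate_pair(filled_spec)
    layout = imaging.build_reference_layout(filled)
    max_ratio_err = 0.0
    max_shift_err = 0
    n_positions = 0
    for seed in seeds:
        rng = np.random.default_rng(seed)
        shift = tuple(int(s) for s in rng.integers(-8, 9, size=2))
        spec = synth.default_plate_spec(seed=seed, noise_sd=noise_sd, shift=shift)
        pre, post, truth = synth.render_plate_pair(spec)
        fitted = imaging.fit_layout(layout, pre, max_shift_px=20)
        offset = fitted.boxes[0, 0, :2] - layout.boxes[0, 0, :2]
        max_shift_err = max(
            max_shift_err,
            int(max(abs(offset[0] - shift[0]), abs(offset[1] - shift[1]))),
        )
        g_pre = imaging.measure_grid(pre, fitted, [(7, 11)])
        g_post = imaging.measure_grid(post, fitted, [(7, 11)])
        table = imaging.adhesion_from_pair(g_pre, g_post)
        merged = table.merge(truth, on=["row", "col"], suffixes=("_m", "_t"))
        grown = merged[merged["expected_pre"] >= min_pre_density]
        n_positions += len(grown)
        max_ratio_err = max(
            max_ratio_err, float((grown["ratio_m"] - grown["ratio_t"]).abs().max())
        )
    return {
        "max_ratio_error": max_ratio_err,
        "max_shift_error_px": max_shift_err,
        "n_plate_pairs": len(list(seeds)),
        "n_positions": n_positions,
    }


def flocculation_metrics(n_seeds: int = 50, base_seed: int = 0) -> dict:
    """One-hot CV closed form, scale invariance, and clump monotonicity."""
    grid = np.zeros((15, 15))
    grid[7, 7] = 1.0
    from .flocculation import WellScan, flocculation_cv

    onehot_cv = flocculation_cv(WellScan("w", grid)).cv
    # power-of-two rescaling keeps every floating-point operation exact
    scaled_cv = flocculation_cv(WellScan("w", grid * 32.0)).cv
    medians = {}
    for clump in (0.0, 1.0, 2.0, 4.0):
        cvs = []
        for k in range(n_seeds):
            plate, _ = synth.simulate_plate_scan(clump, n=15, seed=base_seed + k)
            scores = score_plate(plate)
            cvs.append(float(scores.loc[scores.well != "H12", "cv"].median()))
        medians[clump] = float(np.median(cvs))
    ordered = [medians[c] for c in (0.0, 1.0, 2.0, 4.0)]
    return {
        "onehot_cv": float(onehot_cv),
        "scale_invariant": bool(scaled_cv == onehot_cv),
        "median_cv_by_clump": medians,
        "monotone": bool(all(a < b for a, b in zip(ordered, ordered[1:]))),
    }


def permutation_calibration(
    n_runs: int = 2000,
    n_per_group: int = 50,
    alpha: float = 0.05,
    n_perm: int = 500,
    seed: int = 0,
) -> dict:
    """Empirical type-I error of the permutation test on i.i.d. normal nulls."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for i in range(n_runs):
        x = rng.standard_normal(n_per_group)
        y = rng.standard_normal(n_per_group)
        result = screenstats.permutation_t_test(
            x, y, n_perm=n_perm, alternative="two-sided", seed=int(rng.integers(2**31 - 1))
        )
        rejections += result.p <= alpha
    return {"type_i_error": rejections / n_runs, "n_runs": n_runs}


def consequence_agreement(seed: int = 1) -> dict:
    """Category/length agreement of the caller with construction-time labels."""
    genome, genes, variants, truth = synth.toy_genome(seed=seed)
    by_id = {g.gene_id: g for g in genes}
    total = agree = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for variant, row in zip(variants, truth.itertuples()):
            if not row.gene:
                continue
            total += 1
            call = varianteffects.classify_variant(genome, by_id[row.gene], variant)
            agree += (
                call.category == row.category
                and call.protein_length_ref == row.protein_length_ref
                and call.protein_length_alt == row.protein_length_alt
                and call.premature_stop == row.premature_stop
            )
    return {
        "agreement_pct": 100.0 * agree / total,
        "n_coding_variants": total,
        "n_variants": len(variants),
    }


def _impute_brute_force(row: list) -> list:
    out = list(row)
    for i, v in enumerate(row):
        if pd.notna(v):
            continue
        left = next((row[j] for j in range(i - 1, -1, -1) if pd.notna(row[j])), None)
        right = next((row[j] for j in range(i + 1, len(row)) if pd.notna(row[j])), None)
        if left is not None and right is not None and left == right:
            out[i] = left
    return out


def imputation_agreement(n_matrices: int = 100, seed: int = 0) -> dict:
    """Flank-agreement imputation vs a direct outward-scan recomputation."""
    rng = np.random.default_rng(seed)
    matching = 0
    for _ in range(n_matrices):
        rows = rng.choice(["P1", "P2", None], size=(10, 25), p=[0.4, 0.4, 0.2])
        cols = [f"c:{(i + 1) * 10}" for i in range(25)]
        data = pd.DataFrame(rows, columns=cols)
        markers = pd.DataFrame(
            {"chromosome": "c", "pos": [(i + 1) * 10 for i in range(25)]}, index=cols
        )
        out = impute_flanked(varianteffects.GenotypeMatrix(data=data, markers=markers))
        ok = all(
            [None if pd.isna(v) else v for v in out.data.iloc[i]]
            == _impute_brute_force(list(rows[i]))
            for i in range(rows.shape[0])
        )
        matching += ok
    return {"agreement_pct": 100.0 * matching / n_matrices, "n_matrices": n_matrices}


def qtl_recovery(
    seeds: range = range(1, 21),
    n_forests: int = 100,
    n_trees: int = 100,
    n_perm: int = 200,
    alpha: float = 0.05,
) -> dict:
    """Planted-QTL detection rate and permuted-phenotype false-positive rate."""
    detected = 0
    null_any_sig = 0
    for seed in seeds:
        gm, pheno, truth = synth.simulate_cross(synth.CrossSpec(seed=seed))
        blocks, X = qtlrf.collapse_blocks(impute_flanked(gm))
        qtl_idx = next(
            i for i, b in enumerate(blocks) if truth["qtl_marker"] in b.members
        )
        Xn, y = X.to_numpy(float), pheno.to_numpy()
        obs = qtlrf.selection_frequency(
            Xn, y, n_forests=n_forests, n_trees=n_trees, seed=seed * 1000 + 7
        )
        null = qtlrf.permutation_null(
            Xn, y, n_perm=n_perm, n_trees=n_trees, seed=seed * 1000 + 8
        )
        results = qtlrf.qtl_pvalues(obs, null, blocks=blocks, alpha=alpha)
        detected += bool(results["significant"].iloc[qtl_idx])

        rng = np.random.default_rng(seed * 1000 + 9)
        y_perm = rng.permutation(y)
        obs_n = qtlrf.selection_frequency(
            Xn, y_perm, n_forests=n_forests, n_trees=n_trees, seed=seed * 1000 + 10
        )
        null_n = qtlrf.permutation_null(
            Xn, y_perm, n_perm=n_perm, n_trees=n_trees, seed=seed * 1000 + 11
        )
        results_n = qtlrf.qtl_pvalues(obs_n, null_n, blocks=blocks, alpha=alpha)
        null_any_sig += bool(results_n["significant"].any())
    n = len(list(seeds))
    return {
        "detection_rate_pct": 100.0 * detected / n,
        "null_any_significant_pct": 100.0 * null_any_sig / n,
        "n_seeds": n,
    }


def screen_recovery(seed: int = 0, n_strains: int = 3600) -> dict:
    """Hit-caller recovery of planted adhesives in a full-size screen."""
    table, truth = synth.simulate_screen(n_strains=n_strains, seed=seed)
    per_strain = table.groupby("strain")["ratio"].mean()
    cutoff = screenstats.percentile_threshold(per_strain, q=95)
    config = screenstats.HitConfig(
        min_repeats=5, pre_min=0.1, post_min=0.05, ratio_min=cutoff
    )
    hits = screenstats.confirm_hits(table, config)
    merged = hits.merge(truth, on="strain")
    recovered = merged.loc[merged.adhesive, "hit"].mean()
    false_calls = merged.loc[~merged.adhesive, "hit"].mean()
    return {
        "recovery_pct": 100.0 * float(recovered),
        "false_call_pct": 100.0 * float(false_calls),
        "ratio_cutoff": float(cutoff),
        "n_strains": n_strains,
    }
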
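"""End-to-end synthetic pipeline: screen -> ITR -> signature -> survival.

``run_pipeline`` simulates every input from the config seed, runs each
analysis stage, writes all result tables under the output directory and
records a provenance JSON (parameters, package version, output
checksums). Deterministic: the same config yields identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

from . import __version__, io
from .config import RunConfig
from .itr import infer_regulators
from .screen import call_hits, differential_response, loess_normalize
from .signature import (
    build_signature,
    cluster_signature,
    correct_matrix,
    fit_mycn_model,
    mna_separation_test,
)
from .simulate import (
    random_network,
    simulate_cohort,
    simulate_contrasts,
    simulate_screen,
)
from .survival import km_estimate, logrank_test, stratify_by_expression

log = logging.getLogger("wntpipe")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on synthetic data; returns a result bundle dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    bundle: dict = {}
    stage = "simulate-screen"
    try:
        plates, screen_truth = simulate_screen(
            n_genes=config.n_genes,
            gradient_amplitude=config.gradient_amplitude,
            noise_sd=config.screen_noise_sd,
            spikes=[(f"GENE{i + 1:05d}", "induced", -6.0) for i in range(20)],
            seed=config.seed,
        )
        io.write_plates(plates, out / "screen_raw.csv")

        stage = "normalize-screen"
        normalized = loess_normalize(
            plates,
            span=config.span,
            excluded_columns=config.excluded_columns,
            surface=config.surface,
        )
        stage = "call-hits"
        hits = call_hits(
            normalized, threshold_sd=config.threshold_sd, scope=config.hit_scope
        )
        io.write_hit_table(hits, out / "hits.tsv")
        diff = differential_response(
            hits[hits["condition"] == "induced"],
            hits[hits["condition"] == "uninduced"],
        )
        io.write_hit_table(diff, out / "differential_response.tsv")
        bundle["hits"] = hits
        bundle["differential_response"] = diff

        stage = "simulate-contrasts"
        network = random_network(
            n_regulators=config.n_regulators,
            targets_per_regulator=config.targets_per_regulator,
            seed=config.seed + 1,
        )
        io.write_network(network, out / "network.tsv")
        regulator = network.regulators[0]
        activity = {
            f"contrast{i + 1}": {regulator: -1} for i in range(config.n_contrasts)
        }
        tables, _ = simulate_contrasts(
            network,
            activity,
            effect_mu=config.effect_mu,
            noise_sd=config.contrast_noise_sd,
            seed=config.seed + 2,
        )
        stage = "itr"
        itr_all = []
        for contrast, de in tables.items():
            io.write_de_table(de, out / f"de_{contrast}.tsv")
            itr_all.append(
                infer_regulators(
                    network,
                    de,
                    contrast=contrast,
                    de_threshold=config.de_threshold,
                    z_cutoff=config.z_cutoff,
                )
            )
        import pandas as pd

        itr = pd.concat(itr_all, ignore_index=True)
        io.write_itr_results(itr, out / "itr_results.tsv")
        bundle["itr"] = itr

        stage = "build-signature"
        signature = build_signature(
            itr, regulator, min_contrasts=config.min_contrasts
        )
        io.write_signature(signature, out / "signature.tsv")
        io.write_gmt(io.signature_to_gmt(signature), out / "signature.gmt")
        bundle["signature"] = signature

        stage = "simulate-cohort"
        expr, probe_map, clinical, cohort_truth = simulate_cohort(
            signature,
            n_samples=config.n_samples,
            frac_amplified=config.frac_amplified,
            activity_effect=config.activity_effect,
            noise_sd=config.cohort_noise_sd,
            hazard_ratio_per_unit=config.hazard_ratio_per_unit,
            censor_rate=config.censor_rate,
            seed=config.seed + 3,
        )
        io.write_expression(expr, out / "expression.tsv")
        io.write_probe_map(probe_map, out / "probe_map.tsv")
        io.write_clinical(clinical, out / "clinical.tsv")

        stage = "correct-mycn"
        clin = clinical.set_index("sample")
        model = fit_mycn_model(expr, clin["mycn_expr"], clin["mycn_amp"])
        corrected = correct_matrix(expr, model, clin["mycn_expr"])
        io.write_expression(corrected, out / "expression_mycn_corrected.tsv")

        stage = "cluster-signature"
        groups = cluster_signature(
            corrected,
            signature,
            probe_map=probe_map,
            linkage=config.linkage,
            metric=config.distance,
        )
        groups.labels.to_frame().assign(score=groups.scores).to_csv(
            out / "signature_groups.tsv", sep="\t", index_label="sample"
        )
        sig_probes = probe_map.index[probe_map.isin(signature.genes["gene"])]
        F, p_anova, probe_table = mna_separation_test(
            groups.scores, clin["mycn_amp"], expr=corrected.loc[sig_probes]
        )
        probe_table.to_csv(out / "mna_probe_tests.tsv", sep="\t", index_label="probe")
        bundle["groups"] = groups
        bundle["mna_f"] = F
        bundle["mna_p"] = p_anova

        stage = "survival"
        labels = groups.labels.loc[clinical["sample"]]
        chi2, df, p = logrank_test(
            clinical["time_days"], clinical["event"], labels.to_numpy()
        )
        curves = km_estimate(
            clinical["time_days"], clinical["event"], labels.to_numpy()
        )
        strat = stratify_by_expression(
            groups.scores, clinical, method=config.stratify_method,
            min_group_frac=config.min_group_frac,
        )
        bundle["logrank"] = {"chi2": chi2, "df": df, "p": p}
        bundle["stratification"] = strat
        bundle["curves"] = curves
        survival_summary = {
            "signature_group_logrank_chi2": chi2,
            "signature_group_logrank_p": p,
            "score_split_method": strat.method,
            "score_split_p": strat.p,
            "mna_anova_F": F,
            "mna_anova_p": p_anova,
        }
        (out / "survival_summary.json").write_text(
            json.dumps(survival_summary, indent=2)
        )
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage_files = sorted(f for f in out.iterdir() if f.is_file() and
                         f.name != "provenance.json")
    provenance = {
        "package": "wntpipe",
        "version": __version__,
        "config": config.to_dict(),
        "elapsed_s": round(time.time() - t0, 2),
        "outputs": {f.name: _sha256(f) for f in stage_files},
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    log.info("pipeline finished in %.1fs; outputs in %s", time.time() - t0, out)
    bundle["provenance"] = provenance
    return bundle
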
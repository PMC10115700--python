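"""CSV/JSON readers and writers and the end-to-end workflow driver.

CSV dialects: the response file has a header row of item ids, the first
column holding respondent ids, cells non-negative integers (empty =
missing).  The Q-matrix file has a header row of attribute names and the
first column holding item ids, cells 0/1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classification import classify, lens_analysis, sumscore_scatter
from .data import (
    AlignmentError,
    InvalidQMatrixError,
    QMatrix,
    ResponseMatrix,
    check_alignment,
    profile_matrix,
)
from .estimation import fit_cdm, standard_errors
from .measurement import discrimination
from .structural import fit_loglinear, marginals
from .validation import lrt, mesa_data, rmsea2, suggest_qvector, wald_select_item

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full workflow run."""

    responses: str = None
    qmatrix: str = None
    outdir: str = "cdm_results"
    item_model_policy: str = "wald-select"  # saturated | wald-select
    structural_order: int = None  # None -> choose by LRT among 1..K and saturated
    epsilon: float = 0.95
    alpha: float = 0.05
    tol: float = 1e-4
    max_iter: int = 2000
    seed: int = None
    dichotomize: bool = True
    accept_suggestions: list = field(default_factory=list)  # item ids whose suggested q-vector to adopt

    def __post_init__(self):
        if not (0 < self.epsilon <= 1):
            raise ValueError("epsilon must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def read_responses_csv(path, dichotomize: bool = True) -> ResponseMatrix:
    df = pd.read_csv(path, index_col=0)
    if dichotomize:
        return ResponseMatrix.from_ordinal(df)
    from .data import complete_cases

    clean, ids, n_removed = complete_cases(df.to_numpy(dtype=float),
                                           [str(i) for i in df.index])
    return ResponseMatrix(values=clean, respondent_ids=ids,
                          item_ids=[str(c) for c in df.columns], n_removed=n_removed)


def write_responses_csv(responses: ResponseMatrix, path) -> None:
    responses.to_frame().to_csv(path, index_label="respondent")


def read_qmatrix_csv(path) -> QMatrix:
    df = pd.read_csv(path, index_col=0)
    arr = df.to_numpy()
    bad = np.argwhere(~np.isin(arr, [0, 1]))
    if bad.size:
        r, c = bad[0]
        raise InvalidQMatrixError(
            f"non-binary Q-matrix cell at item {df.index[r]!r}, attribute {df.columns[c]!r}"
        )
    return QMatrix(entries=arr, item_ids=[str(i) for i in df.index],
                   attribute_names=[str(c) for c in df.columns])


def write_qmatrix_csv(Q: QMatrix, path) -> None:
    Q.to_frame().to_csv(path, index_label="item")


def write_posteriors_csv(fitted, path) -> None:
    K = fitted.K
    labels = ["".join(map(str, row)) for row in profile_matrix(K)]
    pd.DataFrame(fitted.posteriors, columns=labels).to_csv(path, index_label="respondent")


def read_inputs(config: RunConfig):
    """Load and align the response and Q-matrix CSVs for a run."""
    responses = read_responses_csv(config.responses, dichotomize=config.dichotomize)
    Q = read_qmatrix_csv(config.qmatrix)
    check_alignment(responses, Q)
    return responses, Q


def fitted_to_dict(fitted, ses=None) -> dict:
    items = []
    for j, it in enumerate(fitted.items):
        d = {
            "item_id": it.item_id,
            "model": it.model_label,
            "qvector": it.qvector.tolist(),
            "probs": np.round(it.probs, 6).tolist(),
            "discrimination": round(discrimination(it), 6),
        }
        if it.link_params is not None:
            d["link_params"] = np.round(it.link_params, 6).tolist()
        if ses is not None:
            d["ses"] = np.round(ses.item_ses(j), 6).tolist()
        items.append(d)
    struct = {
        "model_order": int(fitted.structural.model_order),
        "probs": np.round(fitted.structural.probs, 8).tolist(),
        "marginals": np.round(marginals(fitted.structural), 6).tolist(),
    }
    if fitted.structural.lambdas is not None:
        struct["lambdas"] = dict(zip(fitted.structural.lambda_labels,
                                     np.round(fitted.structural.lambdas, 4)))
        if fitted.structural.lambda_ses is not None:
            struct["lambda_ses"] = dict(zip(fitted.structural.lambda_labels,
                                            np.round(fitted.structural.lambda_ses, 4)))
    return {
        "schema_version": 1,
        "loglik": fitted.loglik,
        "npar": fitted.npar,
        "n_iterations": fitted.n_iterations,
        "converged": bool(fitted.converged),
        "fit": fitted.fit,
        "items": items,
        "structural": struct,
    }


def run_workflow(config: RunConfig, responses: ResponseMatrix = None, Q: QMatrix = None) -> dict:
    """Execute the full diagnostic workflow and write a results bundle.

    Stages: saturated fit -> Q-validation report -> optional accepted
    q-vector edits with re-fit -> item-level Wald selection -> structural
    comparison by LRT -> final fit -> classification and accuracy ->
    lens/RMSD analysis.  Every stage's output lands in ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": {k: v for k, v in asdict(config).items()}, "stages": []}
    results = {}
    try:
        if responses is None or Q is None:
            responses, Q = read_inputs(config)
        manifest["stages"].append("read_inputs")

        logger.info("fitting saturated G-DINA model (N=%d, J=%d, K=%d)",
                    responses.N, Q.J, Q.K)
        sat = fit_cdm(responses, Q, structural="saturated", tol=config.tol,
                      max_iter=config.max_iter, seed=config.seed)
        results["saturated"] = sat
        manifest["stages"].append("saturated_fit")

        # Q-matrix validation report
        rows = []
        for j, item_id in enumerate(Q.item_ids):
            md = mesa_data(item_id, sat, responses, epsilon=config.epsilon)
            sq, sv = suggest_qvector(item_id, sat, responses, epsilon=config.epsilon)
            rows.append({
                "item": item_id,
                "original_qvector": "".join(map(str, Q.qvector(j))),
                "original_pvaf": round(md.original_pvaf, 4),
                "suggested_qvector": "".join(map(str, sq)),
                "suggested_pvaf": round(sv, 4),
                "best_pvaf_by_size": [round(v, 4) for v in md.best_pvafs],
            })
        qval = pd.DataFrame(rows)
        qval.to_csv(outdir / "q_validation.csv", index=False)
        results["q_validation"] = qval
        manifest["stages"].append("q_validation")

        if config.accept_suggestions:
            entries = Q.entries.copy()
            for item_id in config.accept_suggestions:
                j = Q.item_ids.index(item_id)
                sq, _ = suggest_qvector(item_id, sat, responses, epsilon=config.epsilon)
                entries[j] = sq
                logger.info("accepted suggested q-vector for %s", item_id)
            Q = QMatrix(entries=entries, item_ids=Q.item_ids,
                        attribute_names=Q.attribute_names)
            sat = fit_cdm(responses, Q, structural="saturated", tol=config.tol,
                          max_iter=config.max_iter, seed=config.seed)
            results["saturated"] = sat
            manifest["stages"].append("qmatrix_edit_refit")

        ses = standard_errors(sat, responses)
        if config.item_model_policy == "wald-select":
            labels = []
            wald_rows = []
            for j, item_id in enumerate(Q.item_ids):
                if int(Q.qvector(j).sum()) < 2:
                    labels.append("GDINA")
                    continue
                wr = wald_select_item(sat, responses, item_id, alpha=config.alpha, ses=ses)
                labels.append(wr.selected)
                for lab, (W, df, p) in wr.tests.items():
                    wald_rows.append({"item": item_id, "candidate": lab,
                                      "W": round(W, 4), "df": df, "p": round(p, 4),
                                      "selected": lab == wr.selected})
            pd.DataFrame(wald_rows).to_csv(outdir / "wald_selection.csv", index=False)
            results["item_models"] = labels
            manifest["stages"].append("wald_selection")
        else:
            labels = ["GDINA"] * Q.J
            results["item_models"] = labels

        reduced = fit_cdm(responses, Q, item_models=labels, structural="saturated",
                          tol=config.tol, max_iter=config.max_iter, seed=config.seed)
        results["reduced"] = reduced
        if any(l != "GDINA" for l in labels):
            results["lrt_items"] = lrt(reduced, sat)
        manifest["stages"].append("reduced_fit")

        # structural comparison: orders 1..K-1 against saturated
        struct_rows = []
        chosen_order = config.structural_order
        struct_fits = {}
        for order in range(1, Q.K):
            f_ord = fit_cdm(responses, Q, item_models=labels, structural=order,
                            tol=config.tol, max_iter=config.max_iter, seed=config.seed)
            struct_fits[order] = f_ord
            t = lrt(f_ord, reduced)
            struct_rows.append({"order": order, "loglik": f_ord.loglik,
                                "AIC": f_ord.fit["AIC"], "LRT_vs_saturated": t.statistic,
                                "df": t.df, "p": t.p_value})
        struct_table = pd.DataFrame(struct_rows)
        struct_table.to_csv(outdir / "structural_comparison.csv", index=False)
        results["structural_comparison"] = struct_table
        if chosen_order is None:
            chosen_order = Q.K  # saturated unless a reduced order fits as well
            for row in struct_rows:  # lowest adequate order wins
                if row["p"] > config.alpha:
                    chosen_order = row["order"]
                    break
        manifest["stages"].append("structural_comparison")

        final = (reduced if chosen_order == Q.K
                 else struct_fits.get(chosen_order)
                 or fit_cdm(responses, Q, item_models=labels, structural=chosen_order,
                            tol=config.tol, max_iter=config.max_iter, seed=config.seed))
        results["final"] = final
        results["structural_order"] = chosen_order
        final_ses = standard_errors(final, responses)
        with open(outdir / "final_fit.json", "w") as fh:
            json.dump(fitted_to_dict(final, final_ses), fh, indent=1)
        m2 = rmsea2(final, responses)
        results["rmsea2"] = m2
        manifest["stages"].append("final_fit")

        cls = classify(responses, final.items, final.structural)
        results["classification"] = cls
        write_posteriors_csv(final, outdir / "posteriors.csv")
        acc = {
            "test_accuracy": round(cls.test_accuracy, 4),
            "attribute_accuracy": np.round(cls.attribute_accuracy, 4).tolist(),
            "prevalence_percent": np.round(cls.prevalence_estimates, 2).tolist(),
            "RMSEA2": round(m2.rmsea2, 4),
            "M2": round(m2.m2, 2),
            "M2_df": m2.df,
        }
        with open(outdir / "classification.json", "w") as fh:
            json.dump(acc, fh, indent=1)
        manifest["stages"].append("classification")

        lens = lens_analysis(responses, final.items, final.structural, Q)
        results["lens"] = lens
        lens.to_frame().to_csv(outdir / "lens.csv", index=False)
        table, corr = sumscore_scatter(responses, Q, cls.eap_attributes)
        corr.to_csv(outdir / "sumscore_correlations.csv")
        results["sumscore_correlations"] = corr
        manifest["stages"].append("lens")
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return results
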
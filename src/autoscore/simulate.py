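"""Seeded generators for every input the pipeline consumes.

The generators emulate the three study substrates without any downloads:

* labeled validation datasets in which a planted signature core is
  coordinately upshifted in the known autophagy-high samples,
* a confounded two-group multi-omics cohort where clinical covariates
  both drive group membership (through a logistic model) and shift a
  fraction of feature means (spurious signal that matching-weight
  balancing should remove), with per-layer planted differential features
  independent of the confounders, and
* a cell-line drug panel with planted monotone expression-AUC
  relationships generated through a Gaussian copula.

Continuous expression is generated on a linear scale (normal noise with a
constant coefficient of variation, floored at a small positive value);
protein/methylation layers are zero-centered normalized values. All
outputs are bit-deterministic under (config, seed): every generator draws
from its own substream ``default_rng([seed, stage])`` so stages can be
re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GeneSet, GeneSetCollection
from .signature import HIGH, LOW, LabeledDataset

# substream tags
_S_VALIDATION, _S_COHORT, _S_DRUGS, _S_PAIRS, _S_IMPUTED = 11, 22, 33, 44, 55


@dataclass(frozen=True)
class Confounder:
    """A clinical covariate driving both group membership and features.

    coef_group enters the group-assignment logit per SD of the covariate;
    coef_feature is the log-scale slope applied to the means of the
    confounded feature fraction.
    """

    name: str
    kind: str = "numeric"  # numeric | binary
    coef_group: float = 0.8
    coef_feature: float = 0.1


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the study-condition defaults."""

    seed: int = 0
    n_genes: int = 2000
    n_samples: int = 600
    signature_size: int = 37
    signature_effect: float = 2.0  # SD shift of signature genes in high samples
    embed_signature: bool = True
    confounders: tuple[Confounder, ...] = (
        Confounder("age"),
        Confounder("sex", kind="binary"),
        Confounder("purity"),
    )
    frac_confounded: float = 0.2  # fraction of features receiving spurious shifts
    #: layer -> (n planted features, effect: FC, difference, or odds ratio)
    planted: dict = field(
        default_factory=lambda: {
            "mRNA": (100, 3.0),
            "miRNA": (20, 2.0),
            "protein": (20, 0.5),
            "methylation": (20, 0.5),
            "mutation": (20, 4.0),
            "SCNA": (20, 4.0),
        }
    )
    layer_sizes: dict = field(
        default_factory=lambda: {
            "mRNA": 2000,
            "miRNA": 300,
            "protein": 200,
            "methylation": 300,
            "mutation": 300,
            "SCNA": 150,
        }
    )
    cv: float = 0.5  # linear-scale coefficient of variation of expression noise
    # drug panel
    n_cell_lines: int = 200
    n_sensitive: int = 20
    n_resistant: int = 20
    n_null_genes: int = 10
    planted_rho: float = 0.6

    def __post_init__(self) -> None:
        if self.signature_size > self.n_genes:
            raise ValueError("signature_size exceeds n_genes")
        if not 0 <= self.frac_confounded <= 1:
            raise ValueError("frac_confounded must be in [0, 1]")
        if not 0 < self.planted_rho < 1:
            raise ValueError("|planted rho| must be < 1")


def _gene_ids(n: int, prefix: str = "g") -> np.ndarray:
    return np.array([f"{prefix}{i:05d}" for i in range(n)])


def gen_labeled_validation_sets(
    cfg: SimConfig,
    n_datasets: int = 6,
    n_lists: int = 6,
    n_signal_lists: int = 4,
    n_per_group: int = 20,
    genes_per_list: int = 80,
) -> tuple[list[LabeledDataset], GeneSetCollection, GeneSet]:
    """Labeled datasets plus candidate lists with a planted consensus core.

    Baseline expression is i.i.d. standard normal per gene; in each
    dataset the truth-core genes are shifted by ``signature_effect`` SD in
    the labeled-high samples. Signal lists are the core plus private
    random padding; noise lists draw from non-core genes only, so the
    planted ground truth stays crisp.
    """
    if n_signal_lists > n_lists:
        raise ValueError("n_signal_lists exceeds n_lists")
    rng = np.random.default_rng([cfg.seed, _S_VALIDATION])
    genes = _gene_ids(cfg.n_genes)
    core = np.sort(rng.choice(genes, size=cfg.signature_size, replace=False))
    non_core = np.setdiff1d(genes, core)

    datasets = []
    for d in range(n_datasets):
        n = 2 * n_per_group
        X = rng.normal(size=(cfg.n_genes, n))
        cols = [f"D{d}_s{i:03d}" for i in range(n)]
        labels = pd.Series([HIGH] * n_per_group + [LOW] * n_per_group, index=cols)
        mat = pd.DataFrame(X, index=genes, columns=cols)
        mat.loc[core, labels == HIGH] += cfg.signature_effect
        datasets.append(LabeledDataset(name=f"dataset{d}", matrix=mat, labels=labels))

    sets = []
    n_pad = max(genes_per_list - cfg.signature_size, 0)
    for i in range(n_lists):
        if i < n_signal_lists:
            pad = rng.choice(non_core, size=n_pad, replace=False)
            members = tuple(np.concatenate([core, pad]))
            sets.append(GeneSet(f"list{i}_signal", "planted core + private genes", members))
        else:
            members = tuple(rng.choice(non_core, size=genes_per_list, replace=False))
            sets.append(GeneSet(f"list{i}_noise", "random genes", members))
    truth = GeneSet("truth_core", "planted consensus signature", tuple(core))
    return datasets, GeneSetCollection(sets), truth


def _continuous_layer(rng, feature_ids, n_samples, hi_mask, z_conf, planted_idx,
                      effect, kind, cv, conf_idx, coef_feature):
    n_feat = len(feature_ids)
    if kind == "fold_change":
        base = rng.uniform(5.0, 15.0, size=n_feat)
        mean = np.tile(base[:, None], (1, n_samples))
        mean[np.ix_(planted_idx, hi_mask)] *= effect
        mean[conf_idx] *= np.exp(coef_feature * z_conf)[None, :]
        X = rng.normal(mean, cv * mean)
        X = np.maximum(X, 0.01)
    else:  # difference scale (protein / methylation style)
        X = rng.normal(size=(n_feat, n_samples))
        X[np.ix_(planted_idx, hi_mask)] += effect
        X[conf_idx] += coef_feature * z_conf[None, :]
    return X


def _binary_layer(rng, feature_ids, n_samples, hi_mask, z_conf, planted_idx,
                  odds_ratio, conf_idx, coef_feature, p_range):
    n_feat = len(feature_ids)
    p0 = rng.uniform(*p_range, size=n_feat)
    logit = np.log(p0 / (1 - p0))[:, None] * np.ones((1, n_samples))
    logit[np.ix_(planted_idx, hi_mask)] += np.log(odds_ratio)
    logit[conf_idx] += coef_feature * z_conf[None, :]
    p = 1.0 / (1.0 + np.exp(-logit))
    return (rng.random((n_feat, n_samples)) < p).astype(float)


def gen_multiomics_cohort(cfg: SimConfig, signature: GeneSet | None = None) -> dict:
    """Confounded two-group cohort with planted per-layer features.

    Returns a dict with keys ``layers`` (layer -> feature x sample
    DataFrame), ``samples`` (covariate table with latent ``group`` and
    ``cancer_type``), ``signature`` (the embedded signature GeneSet, mRNA
    layer) and ``truth`` (DataFrame of planted feature ids and effects).

    When ``signature`` is given, those mRNA gene ids (which must exist in
    the mRNA layer) carry the autophagy shift in latent-high samples, so a
    signature derived on the validation sets scores this cohort
    coherently; otherwise a random set of genes is embedded.
    """
    rng = np.random.default_rng([cfg.seed, _S_COHORT])
    n = cfg.n_samples
    sample_ids = [f"s{i:04d}" for i in range(n)]

    cov = {}
    z_list = []
    logit = np.zeros(n)
    for c in cfg.confounders:
        if c.kind == "binary":
            x = (rng.random(n) < 0.5).astype(float)
            z = (x - 0.5) * 2.0
        else:
            x = rng.normal(size=n)
            z = x
        cov[c.name] = x
        z_list.append(z)
        logit += c.coef_group * z
    group = np.where(rng.random(n) < 1.0 / (1.0 + np.exp(-logit)), "high", "low")
    hi_mask = group == "high"
    # one combined confounder axis drives the spurious feature shifts
    z_conf = np.sum(z_list, axis=0) / max(np.sqrt(len(z_list)), 1.0) if z_list else np.zeros(n)

    samples = pd.DataFrame(cov, index=pd.Index(sample_ids, name="sample_id"))
    samples["group"] = group
    samples["cancer_type"] = "SYN1"

    layers: dict[str, pd.DataFrame] = {}
    truth_rows = []
    embedded = None
    layer_sizes = dict(cfg.layer_sizes)
    layer_sizes["mRNA"] = cfg.n_genes  # mRNA universe shared with the validation sets
    for layer, n_feat in layer_sizes.items():
        ids = _gene_ids(n_feat, prefix={"mRNA": "g", "miRNA": "mir", "protein": "prot",
                                        "methylation": "cpg", "mutation": "mut", "SCNA": "scna"}[layer])
        n_planted, effect = cfg.planted.get(layer, (0, 1.0))
        planted_idx = np.arange(n_planted)
        pool = np.arange(n_planted, n_feat)
        n_conf = int(round(cfg.frac_confounded * len(pool)))
        conf_idx = rng.choice(pool, size=n_conf, replace=False) if n_conf else np.array([], dtype=int)
        coef_feat = float(np.mean([c.coef_feature for c in cfg.confounders])) if cfg.confounders else 0.0
        if layer in ("mRNA", "miRNA"):
            X = _continuous_layer(rng, ids, n, hi_mask, z_conf, planted_idx,
                                  effect, "fold_change", cfg.cv, conf_idx, coef_feat)
        elif layer in ("protein", "methylation"):
            X = _continuous_layer(rng, ids, n, hi_mask, z_conf, planted_idx,
                                  effect, "difference", cfg.cv, conf_idx, coef_feat)
        else:
            p_range = (0.02, 0.2) if layer == "mutation" else (0.05, 0.3)
            X = _binary_layer(rng, ids, n, hi_mask, z_conf, planted_idx,
                              effect, conf_idx, coef_feat, p_range)
        mat = pd.DataFrame(X, index=ids, columns=sample_ids)
        if layer == "mRNA" and cfg.embed_signature and cfg.signature_size:
            # signature genes: a dedicated multiplicative shift in latent-high samples
            if signature is not None:
                missing = [g for g in signature.genes if g not in ids]
                if missing:
                    raise ValueError(f"signature genes absent from mRNA layer: {missing[:5]}")
                sig_idx = np.sort(np.nonzero(np.isin(ids, signature.genes))[0])
            else:
                free = np.setdiff1d(np.setdiff1d(np.arange(n_feat), planted_idx), conf_idx)
                sig_idx = np.sort(rng.choice(free, size=min(cfg.signature_size, len(free)), replace=False))
            shift = np.exp(cfg.signature_effect * cfg.cv)  # effect in noise-SD units
            mat.iloc[sig_idx, hi_mask] = mat.iloc[sig_idx, hi_mask] * shift
            embedded = GeneSet("embedded_signature", "cohort autophagy signature",
                               tuple(ids[sig_idx]))
        for i in planted_idx:
            truth_rows.append({"layer": layer, "feature": ids[i], "effect": effect})
        layers[layer] = mat

    truth = pd.DataFrame(truth_rows, columns=["layer", "feature", "effect"])
    return {"layers": layers, "samples": samples, "signature": embedded, "truth": truth}


def _copula_pair(rng, n: int, rho_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate normal achieving Spearman correlation rho_s."""
    r = 2.0 * np.sin(np.pi * rho_s / 6.0)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    return z[:, 0], z[:, 1]


def gen_drug_panel(cfg: SimConfig) -> dict:
    """Cell-line expression and drug AUC tables with planted correlations.

    Each planted drug pairs with one gene at rank correlation
    +/- ``planted_rho`` through a Gaussian copula; all remaining
    gene-drug combinations are independent. Returns ``expr`` (gene x
    cell line, linear scale), ``auc`` (drug x cell line) and ``truth``
    (gene, drug, rho, label).
    """
    rng = np.random.default_rng([cfg.seed, _S_DRUGS])
    n = cfg.n_cell_lines
    n_planted = cfg.n_sensitive + cfg.n_resistant
    genes = _gene_ids(n_planted + cfg.n_null_genes, prefix="cg")
    drugs = np.array([f"drug{i:03d}" for i in range(n_planted)])
    cells = [f"cl{i:04d}" for i in range(n)]

    expr = pd.DataFrame(rng.normal(size=(len(genes), n)), index=genes, columns=cells)
    auc = pd.DataFrame(rng.normal(size=(len(drugs), n)), index=drugs, columns=cells)
    rows = []
    for i in range(n_planted):
        rho = -cfg.planted_rho if i < cfg.n_sensitive else cfg.planted_rho
        ze, za = _copula_pair(rng, n, rho)
        expr.iloc[i] = ze
        auc.iloc[i] = za
        rows.append({"gene": genes[i], "drug": drugs[i], "rho": rho,
                     "label": "sensitive" if rho < 0 else "resistant"})
    expr = np.exp(expr)  # linear positive scale; Spearman is rank-invariant
    truth = pd.DataFrame(rows, columns=["gene", "drug", "rho", "label"])
    return {"expr": expr, "auc": auc, "truth": truth}


def gen_imputed_drug_response(
    cfg: SimConfig,
    latent: pd.Series,
    n_drugs: int = 50,
    n_sensitive: int = 5,
    n_resistant: int = 5,
    rho: float | None = None,
) -> dict:
    """Imputed per-sample drug responses correlated with a latent score.

    The first ``n_sensitive`` drugs get rank correlation -rho with the
    latent vector, the next ``n_resistant`` +rho; the rest independent.
    """
    rho = cfg.planted_rho if rho is None else rho
    rng = np.random.default_rng([cfg.seed, _S_IMPUTED])
    n = len(latent)
    lat_z = (latent.rank() - 0.5) / n  # uniformized latent
    lat_norm = pd.Series(np.clip(np.sqrt(2) * _erfinv(2 * lat_z - 1), -8, 8), index=latent.index)
    resp = np.empty((n_drugs, n))
    rows = []
    for d in range(n_drugs):
        if d < n_sensitive:
            target = -rho
        elif d < n_sensitive + n_resistant:
            target = rho
        else:
            target = 0.0
        r = 2.0 * np.sin(np.pi * target / 6.0)
        noise = rng.normal(size=n)
        resp[d] = r * lat_norm.to_numpy() + np.sqrt(max(1 - r**2, 0.0)) * noise
        rows.append({"drug": f"idrug{d:03d}", "rho": target,
                     "label": "sensitive" if target < 0 else ("resistant" if target > 0 else "none")})
    imputed = pd.DataFrame(resp, index=[r["drug"] for r in rows], columns=latent.index)
    return {"imputed": imputed, "truth": pd.DataFrame(rows)}


def _erfinv(x: np.ndarray) -> np.ndarray:
    from scipy.special import erfinv

    return erfinv(x)


def gen_regulatory_pairs(
    cfg: SimConfig,
    regulators: list[str],
    targets: list[str],
    density: float = 0.1,
) -> pd.DataFrame:
    """Random bipartite regulator->target pair table at a given density."""
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng([cfg.seed, _S_PAIRS])
    mask = rng.random((len(regulators), len(targets))) < density
    ridx, tidx = np.nonzero(mask)
    return pd.DataFrame(
        {"regulator": np.asarray(regulators)[ridx], "target": np.asarray(targets)[tidx]}
    )
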
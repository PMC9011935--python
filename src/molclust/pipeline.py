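"""End-to-end orchestration: featurize -> engineer -> embed -> scan ->
cluster -> evaluate -> visualize.

Each stage writes its artifact (CSV/JSON/PNG) into the run directory and is
skipped on re-runs when the artifact already exists, so interrupted runs
resume.  Every artifact directory carries the hash of the configuration that
produced it; re-running with a different configuration into the same
directory is refused to keep provenance unambiguous.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, embedding, feature_engineering, featurization
from . import similarity_viz, validation_metrics

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_molecules"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run; echoed into every artifact."""

    input: str = ""
    output_dir: str = "molclust_run"
    smiles_column: str = "smiles"
    id_column: str = "id"
    feature_set: str = "integrated"  # integrated | local | global
    n_local_components: int = 50
    latent_dims: tuple[int, ...] = (16, 32, 64)
    embedder: str = "both"  # ae | vae | both
    beta: float = 1.0
    epochs: int = 100
    batch_size: int = 256
    learning_rate: float = 1e-3
    k_grid: tuple[int, ...] = tuple(range(5, 201, 5))
    clusterers: tuple[str, ...] = ("kmeans", "birch")
    scan_subsample: int = 10_000
    plateau_window: int = 2
    plateau_epsilon: float = 0.01
    tsne_perplexity: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.feature_set not in ("integrated", "local", "global"):
            raise ValueError(f"unknown feature_set {self.feature_set!r}")
        if self.embedder not in ("ae", "vae", "both"):
            raise ValueError(f"unknown embedder {self.embedder!r}")
        for c in self.clusterers:
            if c not in ("kmeans", "birch"):
                raise ValueError(f"unknown clusterer {c!r}")
        if len(self.k_grid) == 0:
            raise ValueError("k_grid must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        for key in ("latent_dims", "k_grid", "clusterers"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def embedder_variants(self) -> list[tuple[str, int]]:
        kinds = {"ae": ["AE"], "vae": ["VAE"], "both": ["AE", "VAE"]}[self.embedder]
        return [(kind, d) for kind in kinds for d in self.latent_dims]


# ---------------------------------------------------------------------------
# input handling


def load_molecules(cfg: RunConfig) -> list[featurization.MoleculeRecord]:
    """Read molecules from a .smi ('SMILES<TAB>id' lines) or delimited file."""
    path = Path(cfg.input)
    records: list[tuple[str, str]] = []
    if path.suffix == ".smi":
        for i, line in enumerate(path.read_text().splitlines()):
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{i}"
            records.append((mol_id, smiles))
    else:
        df = pd.read_csv(path)
        if cfg.smiles_column not in df.columns:
            raise ValueError(f"column {cfg.smiles_column!r} not in {path}")
        ids = (
            df[cfg.id_column].astype(str)
            if cfg.id_column in df.columns
            else [f"mol{i}" for i in range(len(df))]
        )
        records = list(zip(ids, df[cfg.smiles_column].astype(str)))
    return [featurization.parse_smiles(s, mol_id) for mol_id, s in records]


# ---------------------------------------------------------------------------
# stages


def _check_provenance(outdir: Path, cfg: RunConfig) -> None:
    meta_path = outdir / "run_meta.json"
    if meta_path.exists():
        prior = json.loads(meta_path.read_text())
        if prior.get("config_hash") != cfg.config_hash:
            raise RuntimeError(
                f"{outdir} holds artifacts from a different configuration "
                f"({prior.get('config_hash')} != {cfg.config_hash}); refuse to mix"
            )
    else:
        meta_path.write_text(
            json.dumps(
                {"config_hash": cfg.config_hash, "config": cfg.to_dict()},
                indent=2, default=list,
            )
        )


def _stage_featurize(cfg: RunConfig, outdir: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    local_path = outdir / "local_features.csv"
    desc_path = outdir / "descriptors.csv"
    if local_path.exists() and desc_path.exists():
        logger.info("featurize: artifacts present, skipping")
        return pd.read_csv(local_path, index_col=0), pd.read_csv(desc_path, index_col=0)
    t0 = time.time()
    mols = load_molecules(cfg)
    desc_names = featurization.default_descriptor_names()
    local_rows, desc_rows, ids = [], [], []
    for mol in mols:
        atoms = featurization.featurize_atoms(mol)
        bonds = featurization.featurize_bonds(mol)
        local_rows.append(feature_engineering.aggregate_local(atoms, bonds))
        desc_rows.append(
            featurization.compute_global_descriptors(mol, desc_names).values
        )
        ids.append(mol.id)
    local = pd.DataFrame(np.stack(local_rows), index=ids)
    desc = pd.DataFrame(np.stack(desc_rows), index=ids, columns=list(desc_names))
    local.to_csv(local_path)
    desc.to_csv(desc_path)
    (outdir / "featurize_meta.json").write_text(
        json.dumps(
            {
                "config_hash": cfg.config_hash,
                "n_molecules": len(ids),
                "descriptor_count": len(desc_names),
                "descriptor_names": list(desc_names),
                "atom_block_layout": list(featurization.ATOM_BLOCK_LAYOUT),
                "bond_block_layout": list(featurization.BOND_BLOCK_LAYOUT),
                "seconds": time.time() - t0,
            },
            indent=2,
        )
    )
    logger.info("featurize: %d molecules in %.1fs", len(ids), time.time() - t0)
    return local, desc


def _stage_engineer(
    cfg: RunConfig, outdir: Path, local: pd.DataFrame, desc: pd.DataFrame
) -> pd.DataFrame:
    table_path = outdir / "feature_table.csv"
    if table_path.exists():
        logger.info("engineer: artifact present, skipping")
        return pd.read_csv(table_path, index_col=0)
    reduced, evr = feature_engineering.reduce_local_dataset(
        local.values, cfg.n_local_components
    )
    z, constant_cols = feature_engineering.zscore_columns(desc.values)
    if cfg.feature_set == "local":
        table = feature_engineering.assemble_feature_table(
            reduced, np.empty((reduced.shape[0], 0)), []
        )
    elif cfg.feature_set == "global":
        table = feature_engineering.assemble_feature_table(
            np.empty((z.shape[0], 0)), z, list(desc.columns)
        )
    else:
        table = feature_engineering.assemble_feature_table(reduced, z, list(desc.columns))
    df = pd.DataFrame(table.values, index=local.index, columns=table.column_labels)
    df.to_csv(table_path)
    (outdir / "engineer_meta.json").write_text(
        json.dumps(
            {
                "config_hash": cfg.config_hash,
                "n_features": table.n_features,
                "dropped_columns": table.dropped_columns,
                "constant_descriptors": [desc.columns[i] for i in constant_cols],
                "explained_variance_ratio": evr.tolist(),
            },
            indent=2,
        )
    )
    logger.info("engineer: %d x %d feature table", *df.shape)
    return df


def _stage_embed(cfg: RunConfig, outdir: Path, table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    out: dict[str, pd.DataFrame] = {}
    for kind, d in cfg.embedder_variants():
        name = f"{kind}{d}"
        emb_path = outdir / f"embedding_{name}.csv"
        if emb_path.exists():
            out[name] = pd.read_csv(emb_path, index_col=0)
            continue
        tcfg = embedding.TrainingConfig(
            latent_dim=d,
            beta=cfg.beta,
            learning_rate=cfg.learning_rate,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            seed=cfg.seed,
        )
        _, emb, history = embedding.train_autoencoder(
            table.values, tcfg, variational=(kind == "VAE")
        )
        df = pd.DataFrame(
            emb.values, index=table.index, columns=[f"z{i + 1}" for i in range(d)]
        )
        df.to_csv(emb_path)
        hist = pd.DataFrame(history)
        hist.to_csv(outdir / f"loss_{name}.csv", index=False)
        _plot_loss(hist, outdir / f"loss_{name}.png", name)
        logger.info("embed %s: final loss %.4g", name, history[-1]["loss"])
        out[name] = df
    return out


def _plot_loss(hist: pd.DataFrame, path: Path, title: str) -> None:
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.plot(hist["epoch"], hist["loss"], label="total")
    ax.plot(hist["epoch"], hist["reconstruction"], label="reconstruction")
    ax.set_xlabel("epoch")
    ax.set_ylabel("loss")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _representations(
    cfg: RunConfig, table: pd.DataFrame, embeddings: dict[str, pd.DataFrame]
) -> list[tuple[str, str, np.ndarray]]:
    """(label, clusterer, matrix) combinations to scan/cluster/evaluate."""
    combos: list[tuple[str, str, np.ndarray]] = []
    p = table.shape[1]
    for clusterer in cfg.clusterers:
        pretty = {"kmeans": "K-means", "birch": "BIRCH"}[clusterer]
        combos.append((f"{pretty} ({p} features)", clusterer, table.values))
    for name, emb in embeddings.items():
        kind, d = name.rstrip("0123456789"), int(name.lstrip("AVE"))
        combos.append((f"{kind} ({d}) + K-means", "kmeans", emb.values))
    return combos


def _safe(label: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in label).strip("_")


def _stage_cluster_evaluate(
    cfg: RunConfig,
    outdir: Path,
    table: pd.DataFrame,
    embeddings: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    report_path = outdir / "report.csv"
    if report_path.exists():
        logger.info("cluster/evaluate: report present, skipping")
        return pd.read_csv(report_path)
    rows = []
    grid = [k for k in cfg.k_grid if k < table.shape[0]]
    for label, clusterer, X in _representations(cfg, table, embeddings):
        tag = _safe(label)
        scan = clustering.scan_k(
            X,
            k_grid=grid,
            method=clusterer,
            seed=cfg.seed,
            subsample=cfg.scan_subsample,
            cache_path=outdir / f"scan_{tag}.csv",
        )
        _plot_scan(scan, outdir / f"scan_{tag}.png", label)
        k = clustering.select_k(scan, cfg.plateau_window, cfg.plateau_epsilon)
        if clusterer == "kmeans":
            assignment = clustering.kmeans(X, k, seed=cfg.seed)
        else:
            assignment = clustering.birch(X, k)
        pd.DataFrame(
            {"id": table.index, "cluster": assignment.labels}
        ).to_csv(outdir / f"assignment_{tag}.csv", index=False)
        idx = validation_metrics.evaluate_all(X, assignment.labels)
        rows.append(
            {
                "Clustering method": label,
                "#Clusters": assignment.k,
                "Calinski-Harabasz": idx.calinski_harabasz,
                "Silhouette": idx.silhouette,
                "Davies-Bouldin": idx.davies_bouldin,
            }
        )
        logger.info("%s: k=%d CH=%.3f Sil=%.3f DB=%.3f", label, assignment.k,
                    idx.calinski_harabasz, idx.silhouette, idx.davies_bouldin)
    report = pd.DataFrame(rows)
    report.to_csv(report_path, index=False)
    (outdir / "metrics.json").write_text(
        json.dumps({"config_hash": cfg.config_hash, "report": rows}, indent=2)
    )
    return report


def _plot_scan(scan: clustering.SilhouetteScan, path: Path, title: str) -> None:
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.plot(scan.grid, scan.scores, marker="o", ms=3)
    ax.set_xlabel("number of clusters")
    ax.set_ylabel("mean Silhouette score")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _stage_visualize(
    cfg: RunConfig,
    outdir: Path,
    table: pd.DataFrame,
    embeddings: dict[str, pd.DataFrame],
    report: pd.DataFrame,
) -> None:
    import matplotlib.pyplot as plt

    done = outdir / "visualize_done.json"
    if done.exists():
        logger.info("visualize: artifacts present, skipping")
        return
    # best run = highest Silhouette row
    best_row = report.loc[report["Silhouette"].idxmax()]
    best_label = best_row["Clustering method"]
    assignment = pd.read_csv(outdir / f"assignment_{_safe(best_label)}.csv")
    labels = assignment["cluster"].to_numpy()

    # cluster-size distribution
    fig, ax = plt.subplots()
    sizes = pd.Series(labels).value_counts().sort_index()
    ax.bar(sizes.index.astype(str), sizes.values)
    ax.set_xlabel("cluster")
    ax.set_ylabel("number of molecules")
    ax.tick_params(axis="x", labelsize=6)
    fig.tight_layout()
    fig.savefig(outdir / "cluster_sizes.png", dpi=120)
    plt.close(fig)

    # t-SNE of the best embedding (or the feature table for raw methods)
    emb_name = next(
        (
            n
            for n in embeddings
            if best_label.startswith(
                f"{n.rstrip('0123456789')} ({int(n.lstrip('AVE'))})"
            )
        ),
        None,
    )
    coords_src = embeddings[emb_name].values if emb_name else table.values
    perplexity = min(cfg.tsne_perplexity, max(2.0, (len(labels) - 1) / 3 - 1))
    coords = similarity_viz.tsne_2d(coords_src, perplexity=perplexity, seed=cfg.seed)
    similarity_viz.plot_tsne(coords, labels, outdir / "tsne.png")

    # Tanimoto similarity matrix of sampled cluster members + similarity maps
    rng = np.random.default_rng(cfg.seed)
    mols = {m.id: m for m in load_molecules(cfg)}
    ids = assignment["id"].astype(str).to_numpy()
    chosen: list[str] = []
    blocks: list[tuple[int, int]] = []
    eligible = [c for c in sizes.index if sizes[c] >= 4]
    for c in rng.permutation(eligible)[:5]:
        members = rng.permutation(ids[labels == c])[:4]
        blocks.append((len(chosen), len(chosen) + len(members)))
        ref, tests = members[0], members[1:]
        for j, t in enumerate(tests):
            result = similarity_viz.similarity_map_weights(mols[ref], mols[t])
            similarity_viz.render_similarity_map(
                result, mols[t], outdir / f"simmap_c{c}_{j}.png"
            )
        chosen.extend(members)
    if chosen:
        mat = similarity_viz.tanimoto_matrix([mols[i] for i in chosen])
        pd.DataFrame(mat, index=chosen, columns=chosen).to_csv(
            outdir / "tanimoto_matrix.csv"
        )
        similarity_viz.plot_tanimoto_heatmap(
            mat, outdir / "tanimoto_matrix.png", labels=chosen, cluster_blocks=blocks
        )
    done.write_text(json.dumps({"config_hash": cfg.config_hash, "best": best_label}))


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage, resuming from existing artifacts; returns the
    artifact directory."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _check_provenance(outdir, cfg)
    local, desc = _stage_featurize(cfg, outdir)
    table = _stage_engineer(cfg, outdir, local, desc)
    embeddings = _stage_embed(cfg, outdir, table)
    report = _stage_cluster_evaluate(cfg, outdir, table, embeddings)
    _stage_visualize(cfg, outdir, table, embeddings, report)
    logger.info("pipeline complete: %s", outdir)
    return outdir
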
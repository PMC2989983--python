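"""Command-line interface: discover, train, predict, evaluate, simulate.

A thin layer over the library.  Every command writes a ``manifest.json``
next to its outputs recording the tool version, seed, effective configuration
and SHA-256 checksums of the inputs, so deterministic runs can be reproduced
bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import click

from . import __version__, pipeline_eval, rbfn, saap_discovery, sequence_io, synthetic
from .features import per_position_max_fscores
from .pipeline_eval import make_cv_trainer
from .rbfn import FeatureSchema
from .sequence_io import NEGATIVE, POSITIVE

logger = logging.getLogger(__name__)

STRATA = ("S-TM", "S-nonTM", "T-TM", "T-nonTM")


@dataclass
class RunConfig:
    """Tunable parameters of the discovery/training pipeline."""

    window_n: int = 14
    sigma: float = 5.0
    ridge_lambda: float = 0.0
    k_anchor: int = 3
    f_min: float = 0.10
    max_pairs: int = 20
    folds: int = 5
    seed: int = 0
    use_topology: bool = False
    threshold: float = 0.0
    homology: str = "per-fold"
    strata: tuple[str, ...] = STRATA

    def __post_init__(self) -> None:
        if self.window_n < 1:
            raise ValueError("window_n must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0.0 <= self.f_min <= 1.0:
            raise ValueError("f_min must lie in [0, 1]")
        bad = set(self.strata) - set(STRATA)
        if bad:
            raise ValueError(f"unknown strata {sorted(bad)}; allowed: {STRATA}")


_CONFIG_TYPES = {
    "window_n": int,
    "sigma": float,
    "ridge_lambda": float,
    "k_anchor": int,
    "f_min": float,
    "max_pairs": int,
    "folds": int,
    "seed": int,
    "threshold": float,
    "homology": str,
}


def read_run_config(path: str | Path | None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional key=value file plus CLI overrides."""
    values: dict = {}
    if path is not None:
        for lineno, line in enumerate(open(path), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise click.UsageError(f"{path}:{lineno}: expected key=value")
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in _CONFIG_TYPES:
                raise click.UsageError(f"{path}:{lineno}: unknown key {key!r}")
            values[key] = _CONFIG_TYPES[key](raw.strip())
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def write_manifest(out_dir: Path, command: str, config: dict, inputs: list[Path]) -> None:
    manifest = {
        "tool": "glycorbf",
        "version": __version__,
        "command": command,
        "config": config,
        "inputs": {
            str(p): _sha256(p) for p in inputs if p is not None and p.is_file()
        },
    }
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _load_dataset(fasta: Path, sites: Path, topology: Path | None):
    records = sequence_io.read_fasta(fasta)
    annotations = sequence_io.read_sites(sites)
    if topology is not None:
        topo = sequence_io.read_topology(topology)
        sequence_io.attach_topology(records, topo)
    return records, annotations


def _stratum_fragments(records, annotations, n: int):
    """Group (2n+1)-mer fragments by stratum key like "S-TM"."""
    by_id = {rec.id: rec for rec in records}
    grouped: dict[str, list] = {key: [] for key in STRATA}
    for site in annotations:
        rec = by_id[site.protein_id]
        cls = "TM" if rec.is_tm else "nonTM"
        frag = sequence_io.extract_window(rec, site.position, n, label=site.label)
        grouped[f"{site.residue}-{cls}"].append(frag)
    return grouped


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Debug-level logging.")
def main(verbose: bool) -> None:
    """GlycoRBF-style O-linked glycosylation site prediction."""
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


@main.command()
@click.option("--fasta", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--sites", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--topology", type=click.Path(exists=True, path_type=Path))
@click.option("--config", "config_path", type=click.Path(exists=True, path_type=Path))
@click.option("--seed", type=int, default=None)
@click.option("--stratum", "strata", multiple=True, type=click.Choice(STRATA))
@click.option("--out", type=click.Path(path_type=Path), required=True)
def discover(fasta, sites, topology, config_path, seed, strata, out):
    """Discover significant amino-acid pairs per (residue, TM/non-TM) stratum."""
    config = read_run_config(config_path, seed=seed)
    wanted = strata or config.strata
    if topology is None and any(s.endswith("-TM") for s in wanted):
        raise click.UsageError(
            "TM strata requested but no membrane topology given; pass --topology"
        )
    records, annotations = _load_dataset(fasta, sites, topology)
    sequences = {rec.id: rec.sequence for rec in records}
    grouped = _stratum_fragments(records, annotations, config.window_n)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    trainer = make_cv_trainer(
        sequences,
        folds=config.folds,
        seed=config.seed,
        sigma=config.sigma,
        ridge_lambda=config.ridge_lambda,
        homology=config.homology,
    )
    for key in wanted:
        frags = grouped[key]
        n_pos = sum(f.label == POSITIVE for f in frags)
        n_neg = len(frags) - n_pos
        if n_pos < 2 or n_neg < 2:
            msg = f"stratum {key}: too few fragments ({n_pos}+/{n_neg}-); skipped"
            logger.warning(msg)
            log_lines.append(msg)
            continue
        anchor = saap_discovery.select_anchor(frags, k_anchor=config.k_anchor)
        candidates = saap_discovery.enumerate_pairs(frags, anchor, f_min=config.f_min)
        result = saap_discovery.rank_and_select(
            candidates, frags, trainer, max_pairs=config.max_pairs
        )
        residue, cls = key.split("-")
        path = out / f"saaps_{residue}_{cls}.tsv"
        saap_discovery.write_saap_table(result.selected, residue, cls, path)
        log_lines.append(
            f"stratum {key}: anchor {anchor.position:+d} {anchor.residues}; "
            f"{len(candidates)} candidates; selected {len(result.selected)} "
            f"pairs; curve {[(k, round(b, 4)) for k, b in result.curve]}"
        )
        click.echo(log_lines[-1])
    (out / "discovery_log.txt").write_text("\n".join(log_lines) + "\n")
    write_manifest(
        out, "discover", dataclasses.asdict(config), [fasta, sites, topology]
    )


@main.command()
@click.option("--fasta", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--sites", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--topology", type=click.Path(exists=True, path_type=Path))
@click.option("--saaps-dir", type=click.Path(exists=True, path_type=Path),
              help="Directory of saaps_<residue>_<class>.tsv tables from discover.")
@click.option("--config", "config_path", type=click.Path(exists=True, path_type=Path))
@click.option("--out", type=click.Path(path_type=Path), required=True)
def train(fasta, sites, topology, saaps_dir, config_path, out):
    """Train one RBFN model per stratum with data; serialize as JSON archives."""
    config = read_run_config(config_path)
    records, annotations = _load_dataset(fasta, sites, topology)
    grouped = _stratum_fragments(records, annotations, config.window_n)
    out.mkdir(parents=True, exist_ok=True)
    for key in config.strata:
        frags = grouped[key]
        n_pos = sum(f.label == POSITIVE for f in frags)
        if n_pos == 0 or n_pos == len(frags):
            logger.warning("stratum %s: one class only; skipped", key)
            continue
        residue, cls = key.split("-")
        saaps: tuple = ()
        if saaps_dir is not None:
            table = saaps_dir / f"saaps_{residue}_{cls}.tsv"
            if table.exists():
                saaps = tuple(s for _, _, s in saap_discovery.read_saap_table(table))
        X = pipeline_eval.encode_fragments(frags, saaps)
        y = [f.label == POSITIVE for f in frags]
        model = rbfn.fit(
            X,
            y,
            sigma=config.sigma,
            ridge_lambda=config.ridge_lambda,
            feature_schema=FeatureSchema(n=config.window_n, saap_list=saaps),
        )
        rbfn.save_model(model, out / f"model_{residue}_{cls}.json")
        click.echo(f"stratum {key}: trained on {len(frags)} fragments "
                   f"({n_pos} positive), {len(saaps)} SAAP features")
    write_manifest(
        out, "train", dataclasses.asdict(config), [fasta, sites, topology, saaps_dir]
    )


def _load_models(models_dir: Path) -> dict[tuple[str, str], rbfn.RBFNModel]:
    models: dict[tuple[str, str], rbfn.RBFNModel] = {}
    for path in sorted(models_dir.glob("model_*_*.json")):
        _, residue, cls = path.stem.split("_")
        models[(residue, cls)] = rbfn.load_model(path)
    if not models:
        raise click.UsageError(f"no model_<residue>_<class>.json files in {models_dir}")
    return models


@main.command()
@click.option("--fasta", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--topology", type=click.Path(exists=True, path_type=Path))
@click.option("--models", "models_dir", type=click.Path(exists=True, path_type=Path),
              required=True)
@click.option("--use-topology", is_flag=True,
              help="Veto positive calls inside transmembrane segments.")
@click.option("--threshold", type=float, default=0.0,
              help="Positive iff score_pos - score_neg > threshold.")
@click.option("--out", type=click.Path(path_type=Path), required=True)
def predict(fasta, topology, models_dir, use_topology, threshold, out):
    """Score every S/T site of the input proteins."""
    records = sequence_io.read_fasta(fasta)
    if topology is not None:
        sequence_io.attach_topology(records, sequence_io.read_topology(topology))
    models = _load_models(models_dir)
    predictions = []
    for rec in records:
        try:
            predictions.extend(
                pipeline_eval.predict_protein(
                    rec, models, use_topology=use_topology, threshold=threshold
                )
            )
        except KeyError as exc:
            raise click.ClickException(str(exc.args[0])) from exc
    pipeline_eval.write_predictions(predictions, out)
    n_calls = sum(p.decision == POSITIVE for p in predictions)
    click.echo(f"{len(predictions)} candidate sites scored, {n_calls} called positive")
    write_manifest(
        out.parent,
        "predict",
        {"use_topology": use_topology, "threshold": threshold},
        [fasta, topology, models_dir / "manifest.json"
         if (models_dir / "manifest.json").exists() else None],
    )


@main.command()
@click.option("--predictions", type=click.Path(exists=True, path_type=Path),
              required=True)
@click.option("--sites", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--out", type=click.Path(path_type=Path))
def evaluate(predictions, sites, out):
    """Score a predictions table against ground-truth site annotations."""
    truth = {
        (s.protein_id, s.position): s.label for s in sequence_io.read_sites(sites)
    }
    tp = fp = tn = fn = 0
    with open(predictions) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            pid, pos, decision = fields[0], int(fields[1]), fields[6]
            actual = truth.get((pid, pos))
            if actual is None:
                continue
            called = decision == POSITIVE
            positive = actual == POSITIVE
            tp += called and positive
            fp += called and not positive
            tn += not called and not positive
            fn += not called and positive
    metrics = pipeline_eval.compute_metrics(tp, fp, tn, fn)
    report = pipeline_eval.metrics_report({"evaluated": metrics})
    click.echo(report)
    if out is not None:
        rounded = metrics.rounded()
        with open(out, "w") as fh:
            fh.write("#metric\tvalue\n")
            for key, value in rounded.items():
                fh.write(f"{key}\t{value}\n")


_SIM_TYPES = {
    "n_proteins": int,
    "fraction_tm": float,
    "positive_rate": float,
    "seed": int,
    "n_positive_sites": int,
    "n_negative_sites": int,
}


def read_sim_config(path: str | Path | None, seed: int | None = None) -> synthetic.SimConfig:
    """Parse a flat key=value simulation config.

    Ranges use "lo,hi" (length_range, tm_segment_length_range); implanted
    pairs use repeated lines ``implant=anchor_pos,anchor_res,partner_pos,
    partner_residues,penetrance`` with partner fields '-' for anchor-only.
    """
    values: dict = {}
    implants: list[synthetic.ImplantSpec] = []
    if path is not None:
        for lineno, line in enumerate(open(path), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key == "implant":
                a_pos, a_res, p_pos, p_set, pen = [f.strip() for f in raw.split(",")]
                implants.append(
                    synthetic.ImplantSpec(
                        anchor_pos=int(a_pos),
                        anchor_res=a_res,
                        partner_pos=None if p_pos == "-" else int(p_pos),
                        partner_set=() if p_set == "-" else tuple(p_set),
                        penetrance=float(pen),
                    )
                )
            elif key in ("length_range", "tm_segment_length_range"):
                lo, hi = raw.split(",")
                values[key] = (int(lo), int(hi))
            elif key in _SIM_TYPES:
                values[key] = _SIM_TYPES[key](raw)
            else:
                raise click.UsageError(f"{path}:{lineno}: unknown key {key!r}")
    if implants:
        values["implanted_saaps"] = tuple(implants)
    if seed is not None:
        values["seed"] = seed
    return synthetic.SimConfig(**values)


@main.command()
@click.option("--config", "config_path", type=click.Path(exists=True, path_type=Path))
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(path_type=Path), required=True)
def simulate(config_path, seed, out):
    """Generate a synthetic glycoprotein dataset (FASTA + sites + topology)."""
    config = read_sim_config(config_path, seed=seed)
    records, annotations, topology = synthetic.generate(config)
    out.mkdir(parents=True, exist_ok=True)
    sequence_io.write_fasta(records, out / "proteins.fasta")
    sequence_io.write_sites(annotations, out / "sites.tsv")
    sequence_io.write_topology(
        {pid: segs for pid, segs in topology.items() if segs}, out / "topology.tsv"
    )
    n_pos = sum(s.label == POSITIVE for s in annotations)
    click.echo(
        f"{len(records)} proteins, {n_pos} positive and "
        f"{len(annotations) - n_pos} negative sites"
    )
    config_dict = dataclasses.asdict(config)
    config_dict["implanted_saaps"] = [
        dataclasses.asdict(s) for s in config.implanted_saaps
    ]
    write_manifest(out, "simulate", config_dict, [config_path])


if __name__ == "__main__":
    main()
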
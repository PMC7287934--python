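"""Pretrain -> transfer -> fine-tune orchestration with a matched baseline.

The headline protocol: a model is pretrained on the large unclassified
reaction pool, all of its weights are transferred to initialize fine-tuning
on the small classified pool, and an otherwise identical baseline arm is
fine-tuned from fresh random initialization. The two arms share the model
configuration, fine-tuning data, step budget and seed list — only the
initialization differs — so any gap in their test accuracy or in their
validation-accuracy-versus-time curves is attributable to the transferred
weights.

Weight transfer requires the vocabulary (and hence every weight shape) to
be built once over the union of the two corpora and frozen; a mismatch at
transfer time raises rather than silently partially loading.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .data import Corpus, SeqPair, split_8_1_1, to_seq_pairs
from .evaluation import compute_metrics
from .models import ModelConfig, build_model, save_checkpoint
from .beam import predict
from .smiles import detokenize
from .synth import GeneratorConfig, generate_corpora
from .training import train
from .vocab import TokenVocabulary, build_vocabulary

__all__ = ["ExperimentPlan", "ExperimentData", "prepare_data", "pretrain", "finetune", "run_experiment"]


class TransferError(RuntimeError):
    """Architecture or vocabulary mismatch between checkpoint and plan."""


@dataclass
class ExperimentPlan:
    """Full specification of one transfer-versus-baseline experiment."""

    model: ModelConfig = field(default_factory=ModelConfig.desk_transformer)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    pretrain_steps: int = 2000
    finetune_steps: int = 300
    seeds: Tuple[int, ...] = (0, 1, 2)
    use_class_token: bool = False
    beam_width: int = 20
    n_values: Tuple[int, ...] = (1, 2, 3, 5, 10, 20)
    split_seed: int = 0
    eval_limit: int = 200  # test examples scored with the full beam

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seeds"] = list(self.seeds)
        d["n_values"] = list(self.n_values)
        d["generator"]["class_proportions"] = list(self.generator.class_proportions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentPlan":
        d = dict(d)
        d["model"] = ModelConfig.from_dict(d["model"])
        gen = dict(d["generator"])
        gen["class_proportions"] = tuple(gen["class_proportions"])
        d["generator"] = GeneratorConfig(**gen)
        d["seeds"] = tuple(d["seeds"])
        d["n_values"] = tuple(d["n_values"])
        return cls(**d)

    def save(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: Path | str) -> "ExperimentPlan":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class ExperimentData:
    """Prepared corpora, splits and the frozen union vocabulary."""

    vocab: TokenVocabulary
    pretrain_train: List[SeqPair]
    pretrain_valid: List[SeqPair]
    finetune_train: List[SeqPair]
    finetune_valid: List[SeqPair]
    finetune_test: List[SeqPair]


def prepare_data(
    plan: ExperimentPlan,
    large: Optional[Corpus] = None,
    small: Optional[Corpus] = None,
) -> ExperimentData:
    """Generate (or accept) corpora, split 8:1:1 and build the union vocabulary.

    Pretraining pairs never carry class tokens (the large pool is
    unclassified); fine-tuning pairs carry them when the plan asks for it.
    """
    if large is None or small is None:
        large, small = generate_corpora(plan.generator)
    vocab = build_vocabulary([large, small], use_class_token=plan.use_class_token)
    large_split = split_8_1_1(large, seed=plan.split_seed)
    small_split = split_8_1_1(small, seed=plan.split_seed)
    return ExperimentData(
        vocab=vocab,
        pretrain_train=to_seq_pairs(large_split.train, use_class_token=False),
        pretrain_valid=to_seq_pairs(large_split.valid, use_class_token=False),
        finetune_train=to_seq_pairs(small_split.train, use_class_token=plan.use_class_token),
        finetune_valid=to_seq_pairs(small_split.valid, use_class_token=plan.use_class_token),
        finetune_test=to_seq_pairs(small_split.test, use_class_token=plan.use_class_token),
    )


def pretrain(plan: ExperimentPlan, data: ExperimentData, seed: int, log=None):
    """Train on the large pool; returns (model, history)."""
    cfg = replace(plan.model, seed=seed, max_steps=plan.pretrain_steps)
    model = build_model(cfg, data.vocab)
    history, _ = train(model, data.pretrain_train, data.pretrain_valid, log=log)
    return model, history


def finetune(
    plan: ExperimentPlan,
    data: ExperimentData,
    seed: int,
    init: Optional[Dict[str, np.ndarray]] = None,
    init_vocab: Optional[TokenVocabulary] = None,
    log=None,
):
    """Fine-tune on the small pool; ``init=None`` is the fresh-init baseline.

    ``init`` is a pretrained state dict (with ``init_vocab`` for the
    compatibility guard); all weights are loaded, none frozen, and training
    then continues on the fine-tuning split.
    """
    cfg = replace(plan.model, seed=seed, max_steps=plan.finetune_steps)
    model = build_model(cfg, data.vocab)
    if init is not None:
        if init_vocab is not None and init_vocab != data.vocab:
            raise TransferError("vocabulary mismatch between checkpoint and plan")
        try:
            model.load_state_dict(init)
        except ValueError as e:
            raise TransferError(f"cannot transfer weights: {e}") from e
    history, _ = train(model, data.finetune_train, data.finetune_valid, log=log)
    return model, history


def _evaluate_arm(plan: ExperimentPlan, data: ExperimentData, model) -> dict:
    test = data.finetune_test[: plan.eval_limit]
    predictions = predict(
        model, [p.source for p in test], beam_width=plan.beam_width,
        max_len=plan.model.decode_max_len,
    )
    truths = [detokenize(list(p.target)) for p in test]
    labels = [p.class_label for p in test]
    report = compute_metrics(
        predictions,
        truths,
        class_labels=labels if all(l is not None for l in labels) else None,
        n_values=plan.n_values,
        backend=plan.model.eval_backend,
    )
    return report.as_dict()


def run_experiment(plan: ExperimentPlan, outdir: Optional[Path | str] = None, log=None) -> dict:
    """Run both arms for every seed; returns the JSON-serializable report.

    For each seed: pretrain, fine-tune the transfer arm from the pretrained
    weights, fine-tune the baseline arm from scratch, and score both on the
    held-out test split with a beam wide enough for the largest reported N.
    """
    if plan.beam_width < max(plan.n_values):
        raise ValueError("beam_width must cover the largest requested top-N")
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        plan.save(outdir / "plan.yaml")
    data = prepare_data(plan)
    report: dict = {
        "plan": plan.to_dict(),
        "arms": {"baseline": [], "transfer": []},
        "pretrain_histories": [],
    }
    for seed in plan.seeds:
        if log:
            log(f"=== seed {seed}: pretraining ===")
        pre_model, pre_history = pretrain(plan, data, seed, log=log)
        report["pretrain_histories"].append({"seed": seed, "history": pre_history})
        if outdir is not None:
            save_checkpoint(pre_model, outdir / f"pretrained-seed{seed}", history=pre_history)
        pre_state = pre_model.state_dict()
        for arm, init in (("transfer", pre_state), ("baseline", None)):
            if log:
                log(f"=== seed {seed}: fine-tuning ({arm}) ===")
            model, history = finetune(plan, data, seed, init=init, log=log)
            metrics = _evaluate_arm(plan, data, model)
            report["arms"][arm].append(
                {
                    "seed": seed,
                    "init": "pretrained" if init is not None else "fresh",
                    "config": model.config.to_dict(),
                    "history": history,
                    "metrics": metrics,
                }
            )
            if outdir is not None:
                save_checkpoint(model, outdir / f"{arm}-seed{seed}", history=history)
    report["summary"] = summarize(report)
    if outdir is not None:
        (outdir / "report.json").write_text(json.dumps(report, indent=1) + "\n")
        _write_tables(report, outdir)
    return report


def summarize(report: dict) -> dict:
    """Mean and range of top-N accuracy across seeds, per arm."""
    out: dict = {}
    for arm, runs in report["arms"].items():
        by_n: Dict[str, List[float]] = {}
        step0: List[float] = []
        for run in runs:
            for n, v in run["metrics"]["top_n"].items():
                by_n.setdefault(n, []).append(v)
            step0.append(run["history"][0]["valid_top1"])
        out[arm] = {
            "top_n_mean": {n: float(np.mean(v)) for n, v in by_n.items()},
            "top_n_min": {n: float(np.min(v)) for n, v in by_n.items()},
            "top_n_max": {n: float(np.max(v)) for n, v in by_n.items()},
            "step0_valid_top1_mean": float(np.mean(step0)) if step0 else None,
        }
    return out


def _write_tables(report: dict, outdir: Path) -> None:
    """Top-N accuracy table (TSV) and per-arm accuracy-vs-time curves."""
    ns = sorted({int(n) for arm in report["arms"].values() for r in arm for n in r["metrics"]["top_n"]})
    lines = ["model\t" + "\t".join(f"top-{n}" for n in ns)]
    for arm in ("baseline", "transfer"):
        mean = report["summary"][arm]["top_n_mean"]
        lines.append(arm + "\t" + "\t".join(f"{100 * mean[str(n)]:.1f}%" for n in ns))
    (outdir / "topn_table.tsv").write_text("\n".join(lines) + "\n")
    for arm, runs in report["arms"].items():
        for run in runs:
            curve = ["wall_seconds\tvalid_top1"]
            curve += [f"{h['wall_seconds']:.3f}\t{h['valid_top1']:.4f}" for h in run["history"]]
            (outdir / f"curve-{arm}-seed{run['seed']}.tsv").write_text("\n".join(curve) + "\n")
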
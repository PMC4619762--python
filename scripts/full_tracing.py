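"""Full-scale curve-tracing reproduction (hours of CPU time).

Trains networks on the complete curve-tracing task (two equally long
curves of up to five pixels, shaping curriculum, 400-consecutive-correct
criterion) for a batch of seeds, then measures greedy accuracy on 10,000
fresh stimuli at the trained length (5) and at the never-trained length 6.

Run from the repository root:

    python scripts/full_tracing.py --seeds 12 --out scratch/full_tracing

This is deliberately not part of the test suite; the desk-scale checks
use the reduced task (lengths up to 3) exercised by tests/ and
scripts/acceptance.py.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from relearnn import ModelParams
from relearnn.tasks import tracing_curriculum
from relearnn.training import TrainConfig, evaluate_greedy, train


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seeds", type=int, default=12, help="number of networks")
    ap.add_argument("--seed0", type=int, default=0, help="first master seed")
    ap.add_argument("--out", type=Path, default=Path("scratch/full_tracing"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    prm = ModelParams()
    results = []
    for i in range(args.seeds):
        seed = args.seed0 + i
        cfg = TrainConfig(task="tracing", seed=seed)
        res = train(cfg, prm=prm, curriculum=tracing_curriculum(max_length=5))
        acc5 = evaluate_greedy(
            res.weights, res.spec, prm, {"lengths": (5,)}, 10_000,
            np.random.default_rng(10_000 + seed),
        )
        acc6 = evaluate_greedy(
            res.weights, res.spec, prm, {"lengths": (6,)}, 10_000,
            np.random.default_rng(20_000 + seed),
        )
        entry = {
            "seed": seed,
            "reached_criterion": bool(res.reached_criterion),
            "trials_to_criterion": int(res.trials_used),
            "accuracy_length5": acc5,
            "accuracy_length6": acc6,
        }
        results.append(entry)
        print(json.dumps(entry), flush=True)
        res.log.to_csv(args.out / f"trial_log_seed{seed}.csv", index=False)

    trials = [r["trials_to_criterion"] for r in results if r["reached_criterion"]]
    summary = {
        "n_reached": sum(r["reached_criterion"] for r in results),
        "n_seeds": args.seeds,
        "mean_trials": float(np.mean(trials)) if trials else None,
        "range_trials": [int(np.min(trials)), int(np.max(trials))] if trials else None,
        "mean_accuracy_length5": float(np.mean([r["accuracy_length5"] for r in results])),
        "mean_accuracy_length6": float(np.mean([r["accuracy_length6"] for r in results])),
        "results": results,
    }
    (args.out / "summary.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps({k: v for k, v in summary.items() if k != "results"}))


if __name__ == "__main__":
    main()
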
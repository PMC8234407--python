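"""Train the one-against-one SVM and decode fresh trials into commands.

Generates a balanced training set, fits the ten pairwise Gaussian-kernel
classifiers, then runs new noisy trials end to end, printing the decision
score V, the decoded state and the wheelchair command.
"""

import numpy as np

from eogkit import (PipelineConfig, STATES, TraceConfig, decision_score,
                    generate_dataset, generate_trial, process_trace,
                    run_pipeline, train)

trace_cfg = TraceConfig()
pipe_cfg = PipelineConfig()

traces, manifest = generate_dataset(100, trace_cfg, seed=0)
features = np.vstack([process_trace(tr, pipe_cfg).features for tr in traces])
model = train(features, manifest["state"].tolist())
print(f"trained 10 pairwise SVMs, kernel width sigma = {model.sigma:.2f}\n")

for i, state in enumerate(STATES):
    trial = generate_trial(state, trace_cfg, seed=900 + i)
    predicted, event = run_pipeline(trial, model, pipe_cfg)
    v = decision_score(model, process_trace(trial, pipe_cfg).features)
    print(f"actual {state:9s} V={v:+.2f} -> {predicted:9s} command: {event.command}")

print("\nV lands on the interval midpoints (+1.5 left, +0.5 up, -0.5 down, "
      "-1.5 right, 0 straight) when the vote is unanimous; interval "
      "boundaries read as straight gaze.")
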
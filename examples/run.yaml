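# Example pipeline configuration for `riskmine run --config examples/run.yaml`.
# With no corpus_path a synthetic corpus is simulated; point corpus_path at a
# JSONL file of {"id", "text", "label"} records to mine real data.
workdir: riskmine_run
n_messages: 500
seed: 11
model_kind: naive_bayes
confidence_threshold: 0.5
alpha: 1.0
eps: 0.1
min_points: 1
top_k: 10
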
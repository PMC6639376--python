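# corm

Systems-biochemistry analysis of a two-substrate, allosterically regulated
cyclooxygenase network. The enzyme is a functional heterodimer (one catalytic
site, one allosteric site); its two substrates — arachidonic acid (AA) and
2-arachidonoylglycerol (2-AG) — compete for both sites, and the doubly
2-AG-bound complex is catalytically dead. The package provides:

- **`corm.corm_model`** — explicit construction of the 13-species /
  29-reaction mass-action network (9 enzyme occupancy states, 2 substrates,
  2 products), with mass-action rate laws and lossless JSON export.
- **`corm.kinetics`** — stiff ODE integration (LSODA, analytic Jacobian)
  recording concentration and per-reaction rate trajectories, with
  conservation-law guarantees and 10 s steady-state snapshots.
- **`corm.path_analysis`** — integrated net-flux graphs, enumeration of all
  simple substrate-to-product production paths (6 for PG, 4 for PG-G,
  including mixed-product paths through internal turnover edges),
  conservative flux apportionment across paths, and pathway entropy
  landscapes over substrate-concentration grids.
- **`corm.info_theory`** — dose-response tables, plug-in mutual information,
  response entropy, and channel-capacity estimation (quantile binning,
  Blahut–Arimoto maximization, subsample-extrapolation bias correction),
  including per-quadrant capacities and parameter-ensemble sweeps under
  several input-correlation regimes.
- **`corm.synthetic_data`** — thermodynamically consistent (cycle-closed)
  stand-in parameter ensembles with qualitative allosteric constraints,
  substrate input samplers (independent / perfectly correlated / Pearson-r
  targeted copula / fixed-ratio), and toy flux graphs for testing.
- **`corm.workflow_cli`** — a `corm` command with `simulate`, `paths`,
  `entropy`, `capacity` and `ensemble` subcommands writing deterministic,
  provenance-stamped CSV/JSON outputs.

Units are μM and seconds throughout. All rate constants are uncalibrated,
clearly labelled stand-ins (no published posterior is reproduced); analyses
that depend on them are directional/qualitative, not numeric reproductions.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the structural and directional acceptance
checks (network counts, path counts, estimator sanity against closed forms,
dominant-path counts, conservation/property suite, and input-correlation
orderings); the remaining files unit-test each module, with brute-force
oracles in `tests/oracles.py`.

## CLI examples

```sh
corm simulate --outdir out/run --AA0 8 --AG0 8
corm paths    --outdir out/paths
corm entropy  --outdir out/entropy
corm capacity --outdir out/cap --mode correlated_1 --params generate:20 --n-samples 500
corm ensemble --outdir out/ens --n-sets 20
```

Every output directory receives a `config.json` echo of the effective
configuration, and every CSV starts with a `# corm version=... config_hash=...
seed=...` comment; identical configurations reproduce outputs byte-for-byte.

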
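# molmorph

Fingerprint-guided **molecular morphing**: given a start molecule M_S and a
target molecule M_T, the engine applies elementary structural mutation
operators — add/remove atom (AA/RA), add/remove bond (AB/RB), mutate atom
(MA), bond reroute (BR), bond contraction (BC), interlay atom (IA) — and
grows an exploration tree of valid intermediate molecules ("morphs") until it
finds a connected path from M_S to M_T.  The path and its surroundings form a
focused virtual library: structures between two compounds of the same
mechanistic class, candidates for downstream screening in lead discovery.

Each iteration i+1 generates a batch of one-edit morphs from the current
generation M_i, discards those over the molecular-weight cap (default 500 Da)
or the synthetic-accessibility threshold (SAScore ≤ 6 on the 1–10 scale),
scores survivors by their distance to the target,

    d(m) = 1 − sim(fp(m), fp(M_T)),

with Morgan (circular, radius 2, 2048-bit) fingerprints and the Tanimoto
coefficient by default, and accepts morphs by rank: the best K outright, rank
r > K with probability exp(−λ·(r−K)/K), up to a hard cap.  Optional decoy
molecules change the score to the average of the target distance and the
distance to the closest decoy, steering exploration through remoter regions.
Molecules that stay childless for several iterations are pruned with their
subtrees; the search ends when a morph's canonical SMILES equals the
target's.  See `docs/methods.md` for the full model description.

## Worked example

Find a path from aspirin to paracetamol:

```bash
molmorph run --start "CC(=O)Oc1ccccc1C(=O)O" --target "CC(=O)Nc1ccc(O)cc1" \
    --sa-off --n-gen 24 --accept-best 12 --accept-cap 36 \
    --max-iterations 200 --seed 7 --out demo/
```

prints

```
status: found
iterations: 4
path length: 5 molecules; operators: RA -> BC -> BR -> MA
complete: True
```

i.e. the target was reached in 4 iterations by a 4-edit path: the carboxylic
acid loses its hydroxyl (RA), the aldehyde carbon is contracted away (BC),
the acetoxy group migrates to the para position (BR), and the ester oxygen
mutates to the amide nitrogen (MA):

```
CC(=O)Oc1ccccc1C(=O)O  ->  CC(=O)Oc1ccccc1C=O  ->  CC(=O)Oc1ccccc1O
                       ->  CC(=O)Oc1ccc(O)cc1  ->  CC(=O)Nc1ccc(O)cc1
```

`demo/` receives the path as an SDF (`path.sdf`), the full exploration tree
(`tree.json`) and a per-iteration log (`run.log`) with candidate, generated,
filtered, accepted, pruned counts and the best distance.  The same job can be
described in a JSON job file (`molmorph run job.json`).

Other subcommands: `molmorph benchmark` runs the repeated-exploration
protocol over a two-line SMILES+ID pair file (odd line = start, next line =
its target) and reports per-pair mean iterations over successful runs plus
the dataset median; `molmorph neighbourhood` enumerates the bounded one-edit
neighbourhood of an origin molecule; `molmorph layout` computes 2D
coordinates (PCA of fingerprint space, or a stress layout whose pairwise
targets are fingerprint distances) for a tree dump.

The library mirrors the CLI one-to-one:

```python
from molmorph import ExplorationConfig, run
result = run("CC(=O)Oc1ccccc1C(=O)O", "CC(=O)Nc1ccc(O)cc1",
             ExplorationConfig(seed=7))
print(result.complete, result.iterations_used,
      [m.canonical_form for m in result.path.molecules])
```

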
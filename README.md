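# phyloplace

Maximum-likelihood (and maximum-parsimony) placement of anonymous
sequence fragments into fixed reference phylogenies.

Environmental shotgun sequencing produces short nucleotide fragments
whose source lineage is unknown.  For the ~1% of fragments carrying an
informative marker gene, the most accurate way to "bin" them is not a
BLAST vote but a proper phylogenetic insertion: fix a curated reference
tree and alignment, and ask — for every branch — how likely the data
are if the query hangs off that branch.  `phyloplace` implements this
end to end for amino-acid markers:

* **Reference fitting** — Felsenstein-pruning log-likelihood under
  empirical models (WAG default; RtREV, cpREV, Blosum62) with
  4-category discrete-Gamma rates; branch lengths and the Gamma shape α
  optimized on the fixed topology.
* **Placement** — each query is inserted into every branch of the
  (unrooted) reference tree; the three branch lengths at the insertion
  point (distal, proximal, pendant) are re-optimized per branch using
  cached conditional vectors, and the best branch is reported with
  likelihood weight ratios.  A Fitch-parsimony engine offers the same
  interface (faster, somewhat less accurate).
* **Bootstrap with a candidate heuristic** — column-resampling
  replicates re-score only the top 10% of branches ranked on the
  original alignment.
* **Preprocessing** — six-frame translation, profile-score frame
  selection, glocal affine-gap alignment into reference coordinates,
  conserved-block column trimming, and a 50-residue post-trim filter;
  multi-marker fragments are concatenated.
* **Validation harness** — leave-one-out pruning with node-distance
  (≤ 2 nodes = correct) and taxonomy-agreement scoring, plus a
  synthetic-data generator (random trees, simulated alignments,
  planted queries, synthetic genomes) so everything runs with no
  external downloads.

Outputs are standard: jplace v3 for placements, TSV reports, and
2-column per-branch counts ready for tree annotation.

## Worked example

```python
import phyloplace as pp

# a synthetic reference package: 12-leaf tree, 250-column WAG alignment
pkg = pp.simulate_reference_package(pp.SimConfig(n_leaves=12, n_cols=250, seed=42))
model = pp.load_empirical_model("WAG", alpha=1.0)
fit = pp.optimize_all(pkg.tree, pkg.msa, model, estimate_alpha=True)
print(f"reference logL = {fit.log_likelihood_value:.2f}, alpha = {fit.model.alpha:.3f}")

# a query planted on a known branch (pendant 0.05 substitutions/site)
branch = fit.branches[4].branch_id
query, true_branch = pp.plant_query(
    pkg.tree, fit.model, branch, pendant=0.05, length=250, seed=42, query_seed=7
)
result = pp.place_query_ml(fit, query, "frag1")
for s in result.scores[:3]:
    print(f"branch {s.branch_id:2d}  logL {s.log_likelihood:9.2f}  "
          f"lwr {s.like_weight_ratio:.3f}  pendant {s.pendant_length:.4f}")

support = pp.bootstrap_placements(fit, query, pp.BootstrapConfig(100, 0.10, seed=1),
                                  full_result=result)
print("bootstrap support:", {b: round(v, 2) for b, v in support.items()})
```

prints

```
reference logL = -2807.29, alpha = 0.964
branch  4  logL  -2936.35  lwr 1.000  pendant 0.0967
branch  5  logL  -2954.67  lwr 0.000  pendant 0.1282
branch  3  logL  -2954.67  lwr 0.000  pendant 0.1282
bootstrap support: {3: 0.0, 4: 1.0, 5: 0.0}
```

The planted query is recovered on its true branch (4) with all the
likelihood weight and full bootstrap support; the α estimate is close
to the generating value 1.  The `lwr` column is the softmax of the
per-branch log-likelihoods; `pendant` is the optimized length of the
query's own edge.

### Command line

```bash
phyloplace simulate --n-leaves 20 --n-cols 300 --seed 1 --out refpkg/
phyloplace place --refpkg refpkg/ --queries queries.fasta --method ML \
    --bootstrap 100 --seed 1 --out results/
phyloplace validate --n-leaves 16 --targets 3 --seed 1 --out val/
phyloplace aggregate results_part1/ results_part2/ --out merged_counts.tsv
phyloplace trim --alignment alignment.fasta --out mask.tsv
```

`place` writes `placements.jplace`, a per-query TSV and per-branch
counts; `validate` runs the leave-one-out experiment with the ML and MP
engines side by side and prints the accuracy table; `aggregate` merges
split runs (counts add up and may be re-weighted per fragment).

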
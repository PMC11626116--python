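# hingescan

Global hinge sites — the residues that coordinate a protein's slowest,
most cooperative motions — frequently coincide with the sites where drugs
bind. `hingescan` quantifies that coincidence: it detects hinge residues
from Gaussian Network Model (GNM) slow modes (optionally averaged over an
ensemble of drug-bound structural homologs), maps drug-coordinating
residues by heavy-atom contacts, and scores the overlap of the two residue
sets. It is aimed at structural bioinformaticians evaluating
mechanosensitive (hinge) sites as drug-target sites alongside orthosteric
and allosteric ones.

## Method

1. **GNM slow modes.** Residues are Cα nodes; pairs within a cutoff
   (default 10 Å) are linked by identical springs. The Kirchhoff (graph
   Laplacian) matrix Γ is eigendecomposed; mode *k* contributes a variance
   fraction *f*<sub>k</sub> = (1/λ<sub>k</sub>)/Σ<sub>j</sub>(1/λ<sub>j</sub>).
   The smallest *k* with cumulative variance σ ≥ 1/3 is used, capped at 3.
2. **Hinge detection.** Hinge candidates are the residues at sign
   crossovers of each slow-mode profile. Druggability filters then drop
   candidates near chain termini, collapse crossovers inside long
   low-amplitude rigid blocks onto the block boundaries, and annex a short
   run of near-zero neighbours to each surviving crossover.
3. **Ensemble signature profiles.** Homologs passing identity/z-score/RMSD
   filters are mapped to the reference numbering; each member's modes are
   matched one-to-one to the reference modes by eigenvector overlap (sign
   aligned) and averaged into a mean ± SD signature profile, on which
   hinges are called.
4. **Binding sites.** A residue binds a drug when any heavy atom is within
   4.5 Å of a drug heavy atom; contacts are consolidated across drug-bound
   members with a frequency threshold (default 10%).
5. **Overlap statistics.** With *N* residues, *h* hinges, *b* binding
   residues and *s* = |hinge ∩ binding|, significance is the
   hypergeometric tail
   *P* = 1 − Σ<sub>i&lt;s</sub> C(b,i)·C(N−b,h−i)/C(N,h),
   and the enrichment of hinges inside binding sites is
   *e* = s(N−b)/[b(h−s)] (e &gt; 1 ⇔ s &gt; hb/N).

## Worked example

Score a published overlap — the angiotensin-converting enzyme ensemble,
where 12 of 80 hinge residues fall among 43 drug-binding residues out of
598:

```
$ hingescan overlap -n 598 -h 80 -b 43 -s 12
{"N": 598, "P": 0.006783086976421486, "b": 43, "e": 2.2777017783857727, "h": 80, "s": 12}
```

The overlap is far from random (*P* ≈ 6.8 × 10⁻³) and hinge residues are
2.3-fold enriched inside the binding site.

Full pipeline on a synthetic two-domain fixture with a planted hinge
(linker) and a planted ligand pocket:

```
$ hingescan synth --seed 1 --out dumbbell.pdb
$ hingescan run dumbbell.pdb --drug-codes DRG --out-dir out/
{"N": 86, "P": 0.0016415868673050615, "b": 4, "e": Infinity, "h": 2, "s": 2}
```

Both detected hinge residues (43, 44 — the linker midpoint) sit inside the
4-residue planted pocket, so s = h = 2 and the enrichment saturates.
Reports (hinge/binding TSVs, viewer selection strings, resolved config)
land in `out/`. `hingescan run-ensemble` does the same from a manifest of
homolog structures, averaging mode profiles before hinge calling.

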
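# famsnn

A simulator for recurrent spiking neural networks that learn with **local,
activity-maximizing plasticity rules** — no backpropagation, no global loss —
and self-organize their hidden neurons into cooperating **families**, one per
input class.

The model is a three-layer network (Poisson input units, a hidden layer of
leaky integrate-and-fire neurons, one output neuron per class) with four
kinds of learnable synapses: feedforward, reciprocal (output back onto
hidden), and lateral inhibition inside the hidden and output layers.  Every
neuron tracks two exponential moving averages of its own spike train — a
fast *instant activity* `a` and a slow *average activity* `θ` — and every
rule is a function of the difference `a − θ`, applied only at spike events,
with lazy exponential weight decay between events:

    feedforward      dw_ij/dt = α (a_i − θ_i) δ(t − t_j)              − w_ij/τ
    reciprocal       dw_kj/dt = β (a_j − θ_j) w_jk δ(t − t_k)         − w_kj/τ
    output lateral   dw_kk'/dt = −γ (a_k − θ_k) δ(t − t_k')           − w_kk'/τ
    hidden lateral   dw_jj'/dt = η (a_j − θ_j)(a_j' − θ_j') δ(t − t_j) − w_jj'/τ

Excitatory weights live in [0, 1], inhibitory in [−1, 0].  The hidden
lateral rule lets co-active neurons relax their mutual inhibition toward 0
(cooperation) while discordant pairs drive it to −1 (competition): pruning
the trained lateral graph from −1 upward yields a nested hierarchy of neuron
families that mirrors the class structure of the inputs.  Training can be
fully supervised (a constant teacher current into the true class's output
neuron), partially supervised (teacher on a short prefix only), or fully
unsupervised.  See `docs/methods.md` for the complete model description and
calibration rationale.

## Worked example

Train the built-in desk-scale experiment — a 256-30-5 network on a 5-class
synthetic prototype task (16×16 images, 5% pixel flip noise, 1,000 Poisson-
coded presentations of 100 ms stimulus + 100 ms silence) — then cluster the
learned hidden lateral weights:

```bash
$ famsnn train --seed 1 --out runs/demo
[   100 images] accuracy 0.920
[   200 images] accuracy 0.950
[   300 images] accuracy 0.930
[   500 images] accuracy 0.950
[  1000 images] accuracy 0.920
final accuracy 0.920 -> runs/demo

$ famsnn cluster --network runs/demo/network.h5 --out runs/clusters
5 families at cutoff -1.00 -> runs/clusters
```

The learning curve shows the network going from chance (0.2) to ≥ 0.9 test
accuracy within a few hundred presentations (periodic evaluations use a
100-image subsample, so individual points carry ±0.03 sampling noise; the
full-test accuracy of this run is higher).  The `cluster` command reports
that at some pruning cutoff the hidden layer splits into exactly 5 connected
components — one family of cooperating neurons per class — and writes the
full nested tree (`families.json`), the per-family class assignment and
purity (`families.csv`), and the forward/reciprocal weight correlation
(`report.json`).

Other commands: `famsnn evaluate` (frozen-weight accuracy of a checkpoint),
`famsnn ablate` (trains the four connectivity variants — feedforward only,
+ output inhibition, + hidden inhibition, + reciprocal — with a shared
seed), `famsnn visualize` (per-class receptive-field maps as the product of
the two feedforward weight matrices), `famsnn synth-data`, and
`famsnn init-config` (write the default YAML config to edit).  Full-scale
runs on the classic handwritten-digit benchmark are supported by pointing
the config's `data` section at local IDX files (`famsnn train --config
mnist.yaml`); at 784-100-10 and 30,400 presentations this is an overnight
CPU job.

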
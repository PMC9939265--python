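# Example configuration for the README walk-through.
# Any omitted field keeps its default; see leksim/params.py.
model:
  n_males: 20
  arena_half_width: 50.0
  formation_steps: 2000
  episode_steps: 500
  p_spont: 0.002
  k_copy: 0.05
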
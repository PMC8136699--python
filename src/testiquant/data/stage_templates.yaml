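# Quantitative stage descriptors per species, transcribed from the published
# stage-by-stage descriptions. Stages III-IX carry the acrosome angle (degrees,
# mean +/- SD) measured over round-spermatid nuclei; stages X-XII carry the
# printed "ratio between the shortest and the longest longitudinal axis" of the
# elongating spermatid head (stored verbatim as printed; the values exceed 1).
# Flags: n_generations = spermatid generations present (2 before spermiation at
# stage VII, 1 after); acrosome_vesicle distinguishes stage I (no visible
# vesicle) from stage II (vesicle present, angle not yet defined);
# spermatids_elongating marks the onset of nuclear elongation (stage IX on);
# meiotic_figures is pathognomonic for stage XII.
a_cursor:
  I:    {n_generations: 2, acrosome_vesicle: false}
  II:   {n_generations: 2, acrosome_vesicle: true}
  III:  {n_generations: 2, angle: {mean: 28.0, sd: 2.0}}
  IV:   {n_generations: 2, angle: {mean: 33.0, sd: 1.0}}
  V:    {n_generations: 2, angle: {mean: 41.0, sd: 3.0}}
  VI:   {n_generations: 2, angle: {mean: 61.0, sd: 4.0}}
  VII:  {n_generations: 2, angle: {mean: 97.0, sd: 2.0}}
  VIII: {n_generations: 1, angle: {mean: 103.0, sd: 3.0}, spermatids_elongating: false}
  IX:   {n_generations: 1, angle: {mean: 105.0, sd: 4.0}, spermatids_elongating: true}
  X:    {n_generations: 1, ratio: {mean: 1.3, sd: 0.1}, spermatids_elongating: true}
  XI:   {n_generations: 1, ratio: {mean: 1.9, sd: 0.2}, spermatids_elongating: true}
  XII:  {n_generations: 1, ratio: {mean: 2.9, sd: 0.2}, spermatids_elongating: true, meiotic_figures: true}

a_montensis:
  I:    {n_generations: 2, acrosome_vesicle: false}
  II:   {n_generations: 2, acrosome_vesicle: true}
  III:  {n_generations: 2, angle: {mean: 29.0, sd: 2.0}}
  IV:   {n_generations: 2, angle: {mean: 34.0, sd: 1.0}}
  V:    {n_generations: 2, angle: {mean: 44.0, sd: 3.0}}
  VI:   {n_generations: 2, angle: {mean: 61.0, sd: 2.0}}
  VII:  {n_generations: 2, angle: {mean: 92.0, sd: 4.0}}
  VIII: {n_generations: 1, angle: {mean: 102.0, sd: 2.0}, spermatids_elongating: false}
  IX:   {n_generations: 1, angle: {mean: 111.0, sd: 2.0}, spermatids_elongating: true}
  X:    {n_generations: 1, ratio: {mean: 1.8, sd: 0.4}, spermatids_elongating: true}
  XI:   {n_generations: 1, ratio: {mean: 2.5, sd: 0.1}, spermatids_elongating: true}
  XII:  {n_generations: 1, ratio: {mean: 2.8, sd: 0.2}, spermatids_elongating: true, meiotic_figures: true}

n_lasiurus:
  I:    {n_generations: 2, acrosome_vesicle: false}
  II:   {n_generations: 2, acrosome_vesicle: true}
  III:  {n_generations: 2, angle: {mean: 41.0, sd: 3.0}}
  IV:   {n_generations: 2, angle: {mean: 44.0, sd: 2.0}}
  V:    {n_generations: 2, angle: {mean: 54.0, sd: 2.0}}
  VI:   {n_generations: 2, angle: {mean: 61.0, sd: 3.0}}
  VII:  {n_generations: 2, angle: {mean: 78.0, sd: 4.0}}
  VIII: {n_generations: 1, angle: {mean: 86.0, sd: 4.0}, spermatids_elongating: false}
  IX:   {n_generations: 1, angle: {mean: 95.0, sd: 5.0}, spermatids_elongating: true}
  X:    {n_generations: 1, ratio: {mean: 2.3, sd: 0.1}, spermatids_elongating: true}
  XI:   {n_generations: 1, ratio: {mean: 2.5, sd: 0.1}, spermatids_elongating: true}
  XII:  {n_generations: 1, ratio: {mean: 2.8, sd: 0.1}, spermatids_elongating: true, meiotic_figures: true}

o_nigripes:
  I:    {n_generations: 2, acrosome_vesicle: false}
  II:   {n_generations: 2, acrosome_vesicle: true}
  III:  {n_generations: 2, angle: {mean: 44.0, sd: 2.0}}
  IV:   {n_generations: 2, angle: {mean: 54.0, sd: 2.0}}
  V:    {n_generations: 2, angle: {mean: 57.0, sd: 2.0}}
  VI:   {n_generations: 2, angle: {mean: 73.0, sd: 2.0}}
  VII:  {n_generations: 2, angle: {mean: 83.0, sd: 2.0}}
  VIII: {n_generations: 1, angle: {mean: 93.0, sd: 4.0}, spermatids_elongating: false}
  IX:   {n_generations: 1, angle: {mean: 106.0, sd: 2.0}, spermatids_elongating: true}
  X:    {n_generations: 1, ratio: {mean: 1.5, sd: 0.1}, spermatids_elongating: true}
  XI:   {n_generations: 1, ratio: {mean: 1.8, sd: 0.1}, spermatids_elongating: true}
  XII:  {n_generations: 1, ratio: {mean: 2.5, sd: 0.2}, spermatids_elongating: true, meiotic_figures: true}
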
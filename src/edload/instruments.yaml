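# External instrument constants for the comparator crowding indices.
#
# NEDOCS coefficients are transcribed from the published instrument
# (Weiss et al., Acad Emerg Med 2004); the occupied-ventilator/trauma-bay
# term (13.3 per ventilated patient) is omitted in the modified form
# implemented here. Time variables are in hours. The score is floored at 0.
#
# sICMED: the simplified ICMED is a count of satisfied binary crowding
# criteria. The published item cutoffs are not reproduced here; the items
# below are documented, configurable defaults expressed over the metric
# vector, with the left-without-being-seen and ambulance-offload items
# excluded. `per_bed: true` divides the metric by treatment beds before
# comparing.
nedocs:
  intercept: -20.0
  occupancy: 85.8            # census / treatment beds
  boarder_ratio: 600.0       # boarding admits / hospital beds
  longest_admit_wait: 0.93   # per hour
  longest_waiting_room_wait: 5.64  # per hour
  floor: 0.0

sicmed:
  items:
    occupancy_full:          # every treatment bed occupied
      metric: occupancy_rate
      threshold: 1.0
    long_admit_wait:         # an admitted patient boarding >= 2 h
      metric: longest_admit_wait
      threshold: 2.0
    long_wait_to_be_seen:    # someone waiting >= 1 h for first physician contact
      metric: longest_waiting_room_wait
      threshold: 1.0
    waiting_backlog:         # unseen patients >= 20% of treatment beds
      metric: waiting_count
      threshold: 0.2
      per_bed: true
    slow_physician_contact:  # mean time to physician >= 1 h
      metric: time_to_md
      threshold: 1.0

thresholds:
  mseal_crowding: 4.5            # strict: crowded iff score > 4.5
  workload_crowding: 4.5         # inclusive: mean rating >= 4.5
  nedocs_established: 100.0      # published overcrowding threshold
  nedocs_youden_external: 90.0   # cutoff selected in the external validation
  sicmed_established: 3          # ICMED-family crowding at >= 3 criteria
  occupancy_established: 1.0
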
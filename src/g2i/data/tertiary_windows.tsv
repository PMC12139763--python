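# Domain-anchored search windows for pseudoknot/tertiary pairing partners.
# Each window is [anchor+lo, anchor+hi) in intron-relative coordinates.
# Editable: these placements encode the consensus architecture (partner 1
# first, partner 2 second); min_pairs is the shortest duplex reported.
name	anchor1	lo1	hi1	anchor2	lo2	hi2	min_pairs
alpha	d1_start	10	19	lambda_eps_end	0	9	5
beta	d1_start	18	27	lambda_eps_end	7	16	5
gamma	d2_end	0	8	d6_start	-10	-4	4
delta	d3_start	3	11	d6_start	-6	0	4
epsilon	lambda_eps_end	14	22	five_prime_start	4	10	4
lambda	lambda_eps_start	-5	1	d5_start	-11	-5	4
kappa	d2_start	3	11	d5_start	-7	-1	4
zeta	lambda_eps_end	20	28	d5_loop_start	-1	5	4
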
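# Literature-derived catalogue of pre-rRNA intermediates, mature rRNAs and
# spacer fragments on the 13,351-nt 45SN1 (47S) coordinate system.
# Coordinates are 1-based, inclusive on both ends.
# 21S_S / 21S_L end coordinates are provisional (short/long 21S isoforms).
# The 18S-E extension series is anchored at the 18S 3' boundary (5523):
# the metastable +10/+24/+36/+40/+78 forms reach up to site E (5601 = +78)
# and are trimmed back to 18S-E and finally mature 18S.
name	start	end	category
47S	1	13351	precursor
47S-01	424	13351	precursor
47S-02	1	12990	precursor
45S	424	12990	precursor
34S	1	6472	aberrant
30S	424	6472	precursor
26S	1672	6472	precursor
21S	3655	6472	precursor
21S_S	3655	6378	precursor
21S_L	3655	6459	precursor
21S-C	3655	6150	precursor
18S-E	3655	5523	precursor
18S-E+10	3655	5533	extension-series
18S-E+24	3655	5547	extension-series
18S-E+36	3655	5559	extension-series
18S-E+40	3655	5563	extension-series
18S-E+78	3655	5601	extension-series
18S	3655	5523	mature
36S	5601	12990	aberrant
36S-C	6150	12990	aberrant
32S	6473	12990	precursor
12S	6601	7559	precursor
7S	6601	6862	precursor
5.8S	6601	6757	mature
28S	7925	12990	mature
5ETS-01	1	423	spacer-fragment
ITS1-E-2	5602	6472	spacer-fragment
ITS2-4-3p	7560	7924	spacer-fragment
3ETS	12991	13351	spacer-fragment
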
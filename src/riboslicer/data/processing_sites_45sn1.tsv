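# Catalogue of pre-rRNA processing sites on the 13,351-nt 45SN1 (47S)
# coordinate system.  Positions are 1-based.  "side" records whether the
# cleavage generates read starts, read ends, or both; "provenance" records
# whether the site position comes from the literature catalogue or was
# refined/added by boundary-hub analysis (this-work).
name	position	side	provenance
01	424	both	literature
A0	1672	both	literature
1	3655	both	literature
3	5524	both	literature
E	5601	both	literature
C	6150	both	literature
2	6472	both	literature
B1	6601	both	literature
4'	6757	both	literature
4a	6862	both	literature
4	7559	both	literature
3'	7925	both	literature
02	12990	both	literature
E1	5588	both	this-work
E2	5730	both	this-work
2_1	6378	both	this-work
2_2	6459	both	this-work
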
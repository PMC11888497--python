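Language	Top-1	Top-3	Top-10	Not Ranked	No Diagnosis
English	985	1340	1546	3420	1
Chinese	917	1352	1417	3544	6
Czech	887	1252	1409	3532	26
Dutch	1013	1370	1521	3423	23
German	944	1304	1455	3411	101
Italian	860	1327	1514	3450	3
Japanese	796	1256	1364	3348	255
Spanish	951	1370	1579	3388	0
Turkish	903	1311	1449	3473	45
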
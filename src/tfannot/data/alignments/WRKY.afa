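>WRKY_m1
DDGYNWRKYGQKQVKGSEYPRSYYKCTHPNCPVKKKVERSLDGQITEIVYKG
>WRKY_m2
DDGYNWRKDGQKQVKGSEWPRSYYKCTHPNCPVKKKVERSLDGQITEIVYKG
>WRKY_m3
DDGYNWRKYGQKQVKGSEYPRSYYKCTHPNCPVKKKVERSLDGQITEIVYKG
>WRKY_m4
DDGYNWRKYGQKQVKGGLYPRSYYKCTHPNCPVKKKIWRSLDGTITEIVYKG
>WRKY_m5
LDGNNWRNKWQKQVKGSEYPRSYYKCTHPQCPVKKKVERSLDGQITEIVYVG
>WRKY_m6
DDGYNWRKYGDKQFIGSEYGRSYYKCTHPNCPVKKKKERSLDGQITEIVYLG
>WRKY_m7
DDGYNWRKYGANQLKFSERFRSYYKCTHPACPVPKKVWRSLDGQITEIVYKG
>WRKY_m8
DDYYNWRKDGQKQGKGSEYPRSYYKCTWPGCPVKKKVERSLDGQMTEIVYKH
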